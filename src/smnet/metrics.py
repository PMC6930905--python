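"""Binary graph metrics, null-model normalisation and sparsity curves.

Implements, for an undirected binary graph G with N nodes and K edges:

* global efficiency  E_glob = (1/(N(N-1))) * sum_{i != j} 1/d_ij
* local efficiency   E_loc  = (1/N) * sum_i E_glob(G_i), where G_i is
  the subgraph induced by the neighbours of i (i excluded)
* nodal degree       N_dc(i) = sum_j a_ij
* nodal efficiency   E_nodal(i) = (1/(N-1)) * sum_{j != i} 1/d_ij
* betweenness        N_bc(i) = sum_{j<k, i not in {j,k}} sigma_jk(i)/sigma_jk
  (unnormalised, Brandes' accumulation)

Shortest paths are hop counts; unreachable pairs contribute 1/d = 0, so
all quantities stay finite on the disconnected graphs that arise at low
sparsity.  E_glob of a subgraph with fewer than 2 nodes is defined as 0.

Normalised efficiencies divide by the mean over degree-preserving
random networks (double-edge-swap rewiring), the null model under which
a small-world network shows E~glob close to 1 and E~loc above 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .netbuild import BinaryGraph, ConnectivityMatrix, sparsity_grid, threshold_by_sparsity

logger = logging.getLogger(__name__)


def shortest_paths(G: BinaryGraph | np.ndarray) -> np.ndarray:
    """All-pairs hop-count distances by simultaneous BFS.

    Returns an (N, N) float matrix; unreachable pairs are ``inf``.
    """
    adj = G.adjacency if isinstance(G, BinaryGraph) else np.asarray(G)
    n = adj.shape[0]
    A = adj.astype(bool)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = reached.copy()
    d = 0
    while frontier.any():
        d += 1
        frontier = (frontier @ A) & ~reached
        D[frontier] = d
        reached |= frontier
    return D


def _efficiency_from_distances(D: np.ndarray) -> float:
    n = D.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(G: BinaryGraph | np.ndarray) -> float:
    """Mean inverse shortest path length over ordered node pairs."""
    adj = G.adjacency if isinstance(G, BinaryGraph) else np.asarray(G)
    if adj.shape[0] < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return _efficiency_from_distances(shortest_paths(adj))


def nodal_efficiency(G: BinaryGraph | np.ndarray) -> np.ndarray:
    """Per-node mean inverse distance to every other node."""
    adj = G.adjacency if isinstance(G, BinaryGraph) else np.asarray(G)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency needs at least 2 nodes")
    D = shortest_paths(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(G: BinaryGraph | np.ndarray) -> float:
    """Mean global efficiency of each node's neighbour subgraph."""
    adj = G.adjacency if isinstance(G, BinaryGraph) else np.asarray(G)
    n = adj.shape[0]
    if n < 1:
        raise ValueError("empty graph")
    total = 0.0
    for i in range(n):
        nbrs = np.nonzero(adj[i])[0]
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += _efficiency_from_distances(shortest_paths(sub))
    return total / n


def degree_centrality(G: BinaryGraph | np.ndarray) -> np.ndarray:
    """Node degrees (integer vector summing to 2K)."""
    adj = G.adjacency if isinstance(G, BinaryGraph) else np.asarray(G)
    return adj.sum(axis=1).astype(int)


def betweenness_centrality(G: BinaryGraph | np.ndarray) -> np.ndarray:
    """Unnormalised betweenness over unordered pairs (Brandes)."""
    adj = G.adjacency if isinstance(G, BinaryGraph) else np.asarray(G)
    n = adj.shape[0]
    nbrs = [np.nonzero(adj[i])[0].tolist() for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = [s]
        head = 0
        while head < len(queue):
            v = queue[head]
            head += 1
            stack.append(v)
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(stack):
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in preds[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each unordered pair counted from both endpoints


def rewire_degree_preserving(
    G: BinaryGraph,
    n_swaps_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
    max_tries_factor: int = 20,
) -> BinaryGraph:
    """Degree-preserving randomisation by repeated double-edge swaps.

    Swaps (a-b, c-d) -> (a-d, c-b) are accepted only when they create
    neither self-loops nor multi-edges, so the degree sequence and edge
    count are preserved exactly.  Graphs admitting no valid swap (for
    example a triangle) are returned as a copy.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    adj = G.adjacency.copy()
    edges = G.edge_list()
    k = len(edges)
    if k < 2:
        return BinaryGraph(adj, G.sparsity, G.achieved_sparsity)
    target = n_swaps_per_edge * k
    max_tries = max_tries_factor * target
    accepted = tries = 0
    # draw randomness in blocks; per-call generator overhead dominates otherwise
    batch = max(4 * target, 256)
    pool_e = rng.integers(0, k, size=(batch, 2)).tolist()
    pool_c = (rng.random(batch) < 0.5).tolist()
    cursor = 0
    while accepted < target and tries < max_tries:
        tries += 1
        if cursor >= batch:
            pool_e = rng.integers(0, k, size=(batch, 2)).tolist()
            pool_c = (rng.random(batch) < 0.5).tolist()
            cursor = 0
        e1, e2 = pool_e[cursor]
        coin = pool_c[cursor]
        cursor += 1
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if coin:
            c, d = d, c
        # proposed: a-d and c-b
        if len({a, b, c, d}) < 4:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
        accepted += 1
    if accepted == 0:
        logger.debug("no valid degree-preserving swap found; returning copy")
    return BinaryGraph(adj, G.sparsity, G.achieved_sparsity)


def normalized_efficiencies(
    G: BinaryGraph,
    n_null: int = 100,
    seed: int | np.random.Generator = 0,
    n_swaps_per_edge: int = 10,
) -> tuple[float, float]:
    """(E~glob, E~loc): real-network efficiencies divided by the mean
    over ``n_null`` degree-preserving random networks.

    A zero mean null efficiency yields ``nan`` (flagged, not infinite).
    """
    if G.n_edges < 2:
        raise ValueError("need at least 2 edges for null rewiring")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eg = global_efficiency(G)
    el = local_efficiency(G)
    null_g = np.empty(n_null)
    null_l = np.empty(n_null)
    for i in range(n_null):
        null = rewire_degree_preserving(G, n_swaps_per_edge, rng)
        null_g[i] = global_efficiency(null)
        null_l[i] = local_efficiency(null)
    mg, ml = null_g.mean(), null_l.mean()
    eg_norm = eg / mg if mg > 0 else float("nan")
    el_norm = el / ml if ml > 0 else float("nan")
    if mg <= 0 or ml <= 0:
        logger.warning("mean null efficiency is zero; normalised value undefined")
    return eg_norm, el_norm


def classify_small_world(curves: "MetricCurveSet", glob_tol: float = 0.15) -> bool:
    """Small-world classification of one subject-session from its
    normalised-efficiency curves: grid means (nan-aware, since sparse
    thresholds can leave null local efficiency zero/undefined) must
    satisfy E~loc > 1 and |E~glob - 1| <= glob_tol."""
    if curves.e_glob_norm is None:
        raise ValueError("curves carry no normalised efficiencies")
    eg = float(np.nanmean(curves.e_glob_norm))
    el = float(np.nanmean(curves.e_loc_norm))
    return is_small_world(eg, el, glob_tol)


def is_small_world(eg_norm: float, el_norm: float, glob_tol: float = 0.15) -> bool:
    """Small-world criterion: E~loc > 1 and E~glob within ``glob_tol`` of 1."""
    if not (eg_norm > 0 and el_norm > 0):
        raise ValueError("normalised efficiencies must be positive")
    return bool(el_norm > 1.0 and abs(eg_norm - 1.0) <= glob_tol)


@dataclass
class MetricCurveSet:
    """All metrics as functions of sparsity, plus their AUCs.

    Scalars are curves of length ``len(grid)``; nodal metrics are
    ``len(grid) x N`` arrays.  AUCs are trapezoidal integrals over the
    sparsity grid (a scalar, or a length-N vector for nodal metrics).
    """

    grid: np.ndarray
    e_glob: np.ndarray
    e_loc: np.ndarray
    degree: np.ndarray
    nodal_eff: np.ndarray
    betweenness: np.ndarray
    e_glob_norm: np.ndarray | None = None
    e_loc_norm: np.ndarray | None = None
    auc: dict = field(default_factory=dict)

    def compute_auc(self) -> dict:
        x = self.grid
        self.auc = {
            "e_glob": float(np.trapezoid(self.e_glob, x)),
            "e_loc": float(np.trapezoid(self.e_loc, x)),
            "degree": np.trapezoid(self.degree, x, axis=0),
            "nodal_eff": np.trapezoid(self.nodal_eff, x, axis=0),
            "betweenness": np.trapezoid(self.betweenness, x, axis=0),
        }
        if self.e_glob_norm is not None:
            self.auc["e_glob_norm"] = float(np.trapezoid(self.e_glob_norm, x))
            self.auc["e_loc_norm"] = float(np.trapezoid(self.e_loc_norm, x))
        return self.auc


def curves_and_auc(
    C: ConnectivityMatrix,
    grid: np.ndarray | None = None,
    n_null: int = 0,
    seed: int | np.random.Generator = 0,
    n_swaps_per_edge: int = 10,
) -> MetricCurveSet:
    """Threshold ``C`` at every sparsity in ``grid`` and compute all
    metrics, optionally with null-normalised efficiencies
    (``n_null > 0``), then integrate each metric over the grid."""
    grid = sparsity_grid() if grid is None else np.asarray(grid, float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = C.n_nodes
    m = grid.size
    out = MetricCurveSet(
        grid=grid,
        e_glob=np.empty(m),
        e_loc=np.empty(m),
        degree=np.empty((m, n)),
        nodal_eff=np.empty((m, n)),
        betweenness=np.empty((m, n)),
        e_glob_norm=np.empty(m) if n_null else None,
        e_loc_norm=np.empty(m) if n_null else None,
    )
    for idx, s in enumerate(grid):
        g = threshold_by_sparsity(C, float(s))
        D = shortest_paths(g)
        with np.errstate(divide="ignore"):
            inv = 1.0 / D
        np.fill_diagonal(inv, 0.0)
        out.e_glob[idx] = inv.sum() / (n * (n - 1))
        out.nodal_eff[idx] = inv.sum(axis=1) / (n - 1)
        out.e_loc[idx] = local_efficiency(g)
        out.degree[idx] = degree_centrality(g)
        out.betweenness[idx] = betweenness_centrality(g)
        if n_null:
            eg_n, el_n = normalized_efficiencies(g, n_null, rng, n_swaps_per_edge)
            out.e_glob_norm[idx] = eg_n
            out.e_loc_norm[idx] = el_n
    out.compute_auc()
    return out
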