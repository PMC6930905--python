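"""Independent brute-force oracles for graph metrics.

Everything here works from adjacency-matrix powers: the distance
between j and k is the smallest exponent m with (A^m)_jk > 0, and a
walk of minimal length is necessarily a simple path, so (A^d)_jk counts
shortest paths.  This route shares no code with the package's BFS /
Brandes implementations.
"""

from __future__ import annotations

import numpy as np


def oracle_distances(adj: np.ndarray) -> np.ndarray:
    A = np.asarray(adj, dtype=np.int64)
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    M = np.eye(n, dtype=np.int64)
    for k in range(1, n):
        M = M @ A
        newly = (M > 0) & np.isinf(D)
        D[newly] = k
    return D


def oracle_path_counts(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(distances, sigma) where sigma[j, k] counts shortest j-k paths."""
    A = np.asarray(adj, dtype=np.int64)
    n = A.shape[0]
    D = oracle_distances(A)
    powers = [np.eye(n, dtype=np.int64)]
    for _ in range(n - 1):
        powers.append(powers[-1] @ A)
    sigma = np.zeros((n, n), dtype=np.int64)
    for d in range(1, n):
        at_d = D == d
        sigma[at_d] = powers[d][at_d]
    return D, sigma


def oracle_global_efficiency(adj: np.ndarray) -> float:
    D = oracle_distances(adj)
    n = D.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def oracle_nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    D = oracle_distances(adj)
    n = D.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def oracle_local_efficiency(adj: np.ndarray) -> float:
    adj = np.asarray(adj)
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.nonzero(adj[i])[0]
        if nbrs.size >= 2:
            total += oracle_global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return total / n


def oracle_betweenness(adj: np.ndarray) -> np.ndarray:
    """Direct pair enumeration: sigma_jk(i) = sigma_ji * sigma_ik when
    d_ji + d_ik = d_jk, summed over unordered pairs j < k, j != i != k."""
    D, sigma = oracle_path_counts(adj)
    n = D.shape[0]
    bc = np.zeros(n)
    reachable = np.isfinite(D) & (sigma > 0)
    for i in range(n):
        on_path = (D[:, i][:, None] + D[i, :][None, :]) == D  # j x k through i
        valid = on_path & reachable
        valid[i, :] = valid[:, i] = False
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(valid, sigma[:, i][:, None] * sigma[i, :][None, :] / sigma, 0.0)
        bc[i] = np.triu(contrib, 1).sum()
    return bc


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T
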