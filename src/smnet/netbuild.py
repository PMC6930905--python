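"""Functional network construction.

Weighted ROI extraction, pairwise Pearson correlation and conversion to
binary graphs at fixed network densities (sparsities).  Negative
correlations are never admitted as edges; thresholding keeps the
K = round(S * N(N-1)/2) strongest positive off-diagonal entries, with
deterministic lexicographic tie-breaking, so that edge sets are nested
across increasing sparsity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric matrix of pairwise Pearson r with zeroed diagonal."""

    values: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = v.shape[0]
        if v.shape != (n, n) or not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be square symmetric")
        if np.any(np.abs(v) > 1 + 1e-10):
            raise ValueError("Pearson r entries must lie in [-1, 1]")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", v)
        if self.labels is not None:
            if len(self.labels) != n:
                raise ValueError("label count mismatch")
            object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        labels = self.labels or [f"node{i:02d}" for i in range(self.n_nodes)]
        return pd.DataFrame(self.values, index=labels, columns=list(labels))


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected, unweighted graph from sparsity thresholding."""

    adjacency: np.ndarray  # n x n, {0, 1}, zero diagonal
    sparsity: float  # requested sparsity S
    achieved_sparsity: float = float("nan")

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        n = a.shape[0]
        if a.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        a = a.astype(np.int8)
        object.__setattr__(self, "adjacency", a)
        if np.isnan(self.achieved_sparsity):
            object.__setattr__(
                self,
                "achieved_sparsity",
                self.n_edges / (n * (n - 1) / 2) if n > 1 else 0.0,
            )

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(i.tolist(), j.tolist()))


def extract_roi_timecourse(
    voxel_series: np.ndarray, gm_weights: np.ndarray
) -> np.ndarray:
    """Grey-matter-probability-weighted mean of voxel series.

    Returns sum_v w_v x_v(t) / sum_v w_v per timepoint.
    """
    voxel_series = np.atleast_2d(np.asarray(voxel_series, dtype=float))
    w = np.asarray(gm_weights, dtype=float).ravel()
    if w.size != voxel_series.shape[1]:
        raise ValueError("one weight per voxel required")
    if np.any(w < 0):
        raise ValueError("grey-matter weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("at least one positive weight required")
    return voxel_series @ (w / total)


def extract_all_rois(
    voxel_series: np.ndarray, weight_table: pd.DataFrame
) -> np.ndarray:
    """Apply weighted extraction per ROI given a (voxel, roi, weight) table."""
    rois = np.sort(weight_table["roi"].unique())
    cols = []
    for roi in rois:
        sub = weight_table[weight_table["roi"] == roi]
        if len(sub) == 0:
            raise ValueError(f"ROI {roi} has no voxels")
        cols.append(
            extract_roi_timecourse(
                voxel_series[:, sub["voxel"].to_numpy()], sub["weight"].to_numpy()
            )
        )
    return np.column_stack(cols)


def correlation_matrix(
    ts: np.ndarray, labels: tuple[str, ...] | None = None
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation between ROI time courses."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.where(sd == 0)[0][0])
        name = labels[bad] if labels else f"column {bad}"
        raise ValueError(f"zero-variance ROI time course: {name}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    return ConnectivityMatrix(r, labels)


def sparsity_grid(
    low: float = 0.04, high: float = 0.40, step: float = 0.02
) -> np.ndarray:
    """Inclusive, decimal-safe arithmetic grid of sparsity levels."""
    if not (0 < low <= high) or step <= 0:
        raise ValueError("need 0 < low <= high and step > 0")
    n = int(round((high - low) / step)) + 1
    grid = np.round(low + step * np.arange(n), 10)
    grid = grid[grid <= high + 1e-12]
    if grid.size == 0:
        raise ValueError("empty sparsity grid")
    return grid


def degree_sparsity_curve(C: ConnectivityMatrix, grid: np.ndarray) -> np.ndarray:
    """Node degrees at every sparsity level, computed incrementally.

    Because edge sets are nested across increasing sparsity (same
    ordering and tie-breaking as :func:`threshold_by_sparsity`), degrees
    can be accumulated by adding each level's new edges instead of
    re-thresholding; the result is identical to thresholding at each
    level.  Returns a ``(len(grid), N)`` integer array.
    """
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    v = C.values
    n = C.n_nodes
    iu, ju = np.triu_indices(n, 1)
    r = v[iu, ju]
    order = np.lexsort((ju, iu, -r))
    n_pos = int((r > 0).sum())
    ks = [min(int(np.floor(s * n * (n - 1) / 2 + 0.5)), n_pos) for s in grid]
    deg = np.zeros(n, dtype=int)
    out = np.empty((grid.size, n), dtype=int)
    prev = 0
    for idx, k in enumerate(ks):
        sel = order[prev:k]
        if sel.size:
            deg += np.bincount(iu[sel], minlength=n)
            deg += np.bincount(ju[sel], minlength=n)
        prev = max(prev, k)
        out[idx] = deg
    return out


def threshold_by_sparsity(C: ConnectivityMatrix, S: float) -> BinaryGraph:
    """Binarise: keep the K = round(S*N(N-1)/2) strongest positive edges.

    Negative (and zero) correlations are excluded.  If fewer positive
    entries exist than requested, all positives are kept and the
    achieved sparsity recorded.  Ties at the cutoff are broken toward
    smaller (i, j), so edge sets are nested across sparsities.
    """
    if not 0 < S < 1:
        raise ValueError(f"sparsity {S} must lie in (0, 1)")
    v = C.values
    n = C.n_nodes
    k_target = int(np.floor(S * n * (n - 1) / 2 + 0.5))
    iu, ju = np.triu_indices(n, 1)
    r = v[iu, ju]
    pos = r > 0
    n_pos = int(pos.sum())
    if n_pos < k_target:
        warnings.warn(
            f"only {n_pos} positive correlations available for requested "
            f"K={k_target} at S={S}; keeping all positives",
            stacklevel=2,
        )
    k = min(k_target, n_pos)
    adj = np.zeros((n, n), dtype=np.int8)
    if k > 0:
        order = np.lexsort((ju, iu, -r))  # strongest first, then lexicographic
        keep = order[:k]
        adj[iu[keep], ju[keep]] = 1
        adj = adj | adj.T
    return BinaryGraph(adj, sparsity=S, achieved_sparsity=k / (n * (n - 1) / 2))
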