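"""Node-level activity and connectivity follow-up measures.

ALFF (amplitude of low-frequency fluctuation): the mean, over frequency
bins inside the low-frequency band, of the square root of the
periodogram power -- i.e. the mean amplitude spectrum in 0.01-0.08 Hz.
Computed on series preprocessed identically to the network input, so
the in-band average runs over the band that survives filtering.

Seed-based functional connectivity: Pearson r from a seed node to every
other node, Fisher r-to-z transformed (z = atanh r) for inference.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sp_signal


def alff(
    ts_column: np.ndarray,
    tr_seconds: float,
    band: tuple[float, float] = (0.01, 0.08),
) -> float:
    """Mean amplitude-spectrum value of one time course in ``band``."""
    x = np.asarray(ts_column, dtype=float).ravel()
    if x.size < 16:
        raise ValueError("need at least 16 timepoints for ALFF")
    fs = 1.0 / tr_seconds
    low, high = band
    if not 0 <= low < high <= fs / 2:
        raise ValueError("band must lie within [0, Nyquist]")
    freqs, power = sp_signal.periodogram(x, fs=fs, window="boxcar", detrend=False)
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise ValueError("no frequency bins inside the requested band")
    return float(np.sqrt(power[mask]).mean())


def alff_all_nodes(
    data: np.ndarray, tr_seconds: float, band: tuple[float, float] = (0.01, 0.08)
) -> np.ndarray:
    """ALFF of every column of a (timepoints x nodes) matrix."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return np.array([alff(data[:, j], tr_seconds, band) for j in range(data.shape[1])])


def fc_vector(ts: np.ndarray, seed_node: int) -> np.ndarray:
    """Fisher-z connectivity from ``seed_node`` to every other node.

    Returns a length-N vector with ``nan`` at the seed position; |r| = 1
    entries are carried as ``nan`` with a warning (infinite z).
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    n = ts.shape[1]
    if not 0 <= seed_node < n:
        raise ValueError(f"seed node {seed_node} out of range")
    if np.any(ts.std(axis=0) == 0):
        raise ValueError("zero-variance time course")
    r = np.corrcoef(ts, rowvar=False)[seed_node]
    z = np.full(n, np.nan)
    for j in range(n):
        if j == seed_node:
            continue
        rj = min(max(r[j], -1.0), 1.0)
        if abs(rj) >= 1.0 - 1e-12:
            warnings.warn(
                f"|r| = 1 between nodes {seed_node} and {j}; "
                "Fisher z is infinite, stored as missing",
                stacklevel=2,
            )
            continue
        z[j] = np.arctanh(rj)
    return z
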