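"""Temporal preprocessing of ROI time series.

Implements the temporal stages of a standard resting-state pipeline:
dropping initial volumes, linear detrending, zero-phase band-pass
filtering (0.01-0.08 Hz by default) and nuisance regression with a
Friston-24 motion expansion plus white-matter and CSF signals.  Nuisance
regressors are band-pass filtered with the same operator as the data
before regression, so the regression cannot reintroduce out-of-band
variance.

Spatial stages (realignment, normalisation, segmentation) operate on
images and are outside the scope of this package: inputs here are
already ROI-level (timepoints x nodes) matrices.  All operators are
linear, so they commute with the weighted ROI averaging used for node
definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class SubjectSession:
    """One subject's ROI time-series matrix for one scanning session."""

    subject_id: str
    group: str  # HF | LF | SHAM
    session: str  # pre | post
    data: np.ndarray  # timepoints x n_nodes
    tr_seconds: float

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D (timepoints x nodes) array")
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.group not in {"HF", "LF", "SHAM"}:
            raise ValueError(f"unknown group {self.group!r}")
        if self.session not in {"pre", "post"}:
            raise ValueError(f"unknown session {self.session!r}")
        if data.shape[0] < 2 * data.shape[1]:
            warnings.warn(
                "fewer than 2 timepoints per node; correlation estimates "
                "will be unstable",
                stacklevel=2,
            )
        object.__setattr__(self, "data", data)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class NuisanceSet:
    """Nuisance regressors accompanying one session: 6 rigid-body motion
    parameters plus mean white-matter and CSF signals."""

    motion6: np.ndarray  # timepoints x 6
    wm: np.ndarray  # timepoints
    csf: np.ndarray  # timepoints

    def __post_init__(self):
        motion6 = np.atleast_2d(np.asarray(self.motion6, dtype=float))
        wm = np.asarray(self.wm, dtype=float).ravel()
        csf = np.asarray(self.csf, dtype=float).ravel()
        if motion6.shape[1] != 6:
            raise ValueError("motion6 must have 6 columns")
        if not (motion6.shape[0] == wm.size == csf.size):
            raise ValueError("nuisance series lengths differ")
        object.__setattr__(self, "motion6", motion6)
        object.__setattr__(self, "wm", wm)
        object.__setattr__(self, "csf", csf)

    def discard(self, n: int) -> "NuisanceSet":
        return NuisanceSet(self.motion6[n:], self.wm[n:], self.csf[n:])


def discard_initial_volumes(ts: np.ndarray, n_discard: int = 5) -> np.ndarray:
    """Drop the first ``n_discard`` rows (signal-equilibration volumes)."""
    ts = np.asarray(ts, dtype=float)
    if not 0 <= n_discard < ts.shape[0]:
        raise ValueError(
            f"n_discard={n_discard} must be in [0, {ts.shape[0]})"
        )
    return ts[n_discard:].copy()


def detrend_linear(ts: np.ndarray) -> np.ndarray:
    """Remove, per column, the least-squares fit of intercept + linear term."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 timepoints to detrend")
    return signal.detrend(ts, axis=0, type="linear")


def bandpass(
    ts: np.ndarray,
    low: float = 0.01,
    high: float = 0.08,
    tr_seconds: float = 2.0,
) -> np.ndarray:
    """Zero-phase ideal (frequency-domain) band-pass along the time axis.

    Fourier coefficients of bins outside [low, high] are set to zero and
    the series inverse-transformed -- the construction used by the
    classic resting-state toolchains.  Being an orthogonal projection it
    introduces no phase shift and is exactly idempotent; the DC
    component is always removed.
    """
    ts = np.asarray(ts, dtype=float)
    nyq = 0.5 / tr_seconds
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq:.4g} Hz)"
        )
    n = ts.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    spec = np.fft.rfft(ts, axis=0)
    keep = (freqs >= low) & (freqs <= high)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=0)


def expand_friston24(motion6: np.ndarray) -> np.ndarray:
    """Friston-24 motion expansion: [R, R^2, R(t-1), R(t-1)^2].

    The one-timepoint backward shift is zero-padded at the first row.
    """
    motion6 = np.atleast_2d(np.asarray(motion6, dtype=float))
    if motion6.shape[1] != 6:
        raise ValueError("expected 6 motion columns")
    lag = np.zeros_like(motion6)
    lag[1:] = motion6[:-1]
    return np.hstack([motion6, motion6**2, lag, lag**2])


def regress_nuisance(ts: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """OLS residuals of each data column on [intercept | regressors]."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    if regressors.shape[0] != ts.shape[0]:
        raise ValueError(
            f"regressor length {regressors.shape[0]} != data length "
            f"{ts.shape[0]}"
        )
    X = np.column_stack([np.ones(ts.shape[0]), regressors])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"nuisance design is rank deficient ({rank}/{X.shape[1]}); "
            "redundant columns contribute nothing",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(X, ts, rcond=None)
    return ts - X @ beta


def preprocess_session(
    sess: SubjectSession,
    nuisance: NuisanceSet | None = None,
    n_discard: int = 5,
    low: float = 0.01,
    high: float = 0.08,
) -> SubjectSession:
    """Full temporal pipeline: discard -> detrend -> band-pass -> regress.

    Nuisance regressors (Friston-24 expansion of the motion parameters,
    WM and CSF) are band-pass filtered with the same operator before the
    regression.  Returns a new :class:`SubjectSession`.
    """
    ts = discard_initial_volumes(sess.data, n_discard)
    ts = detrend_linear(ts)
    ts = bandpass(ts, low, high, sess.tr_seconds)
    if nuisance is not None:
        nuis = nuisance.discard(n_discard)
        reg = np.column_stack(
            [expand_friston24(nuis.motion6), nuis.wm, nuis.csf]
        )
        reg = bandpass(reg, low, high, sess.tr_seconds)
        ts = regress_nuisance(ts, reg)
    return replace(sess, data=ts)
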