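"""Synthetic multi-group rTMS cohort generator.

Generates a two-session (pre/post stimulation), three-group (HF = 3 Hz,
LF = 1 Hz, SHAM) cohort of BOLD-like ROI time series over a known
29-node ground-truth network, so that the whole network pipeline can be
exercised and validated without access to scanner data.

The generative model:

* A ground-truth correlation matrix with a 3-community block structure
  (medial SMA/paracentral, left lateral, right lateral sensorimotor
  communities) and a small set of hub nodes with elevated cross-module
  coupling -- enough structure to yield small-world organisation after
  sparsity thresholding.
* Per session, multivariate Gaussian noise is coloured by the Cholesky
  factor of that matrix, band-pass filtered into the analysis band
  (0.01-0.08 Hz), rescaled to unit variance, and white measurement noise
  is added.
* Stimulation effects are planted post-session only: the target node's
  off-diagonal covariance is multiplied by a connectivity-attenuation
  factor (drives degree/betweenness/FC findings) and its signal scale by
  an amplitude-attenuation factor (drives the ALFF finding).  Both are
  modulated per subject by a shared responsiveness exponent, which makes
  connectivity change and amplitude change positively correlated across
  subjects.  The SHAM effect is the identity.

No haemodynamic convolution, spatial smoothness or realistic motion
artefacts are modelled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import (
    LEFT_PCL_ROI,
    RIGHT_SMA_ROI,
    default_modules,
    load_atlas,
    roi_labels,
)
from .preprocess import NuisanceSet, SubjectSession, bandpass

logger = logging.getLogger(__name__)

GROUPS = ("HF", "LF", "SHAM")
SESSIONS = ("pre", "post")


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Known correlation structure from which sessions are sampled."""

    covariance: np.ndarray  # n x n, unit diagonal, PSD
    module_assignment: np.ndarray  # n ints
    hub_nodes: tuple[int, ...]

    def __post_init__(self):
        cov = np.asarray(self.covariance, dtype=float)
        n = cov.shape[0]
        if cov.shape != (n, n) or not np.allclose(cov, cov.T, atol=1e-12):
            raise ValueError("covariance must be square symmetric")
        if not np.allclose(np.diag(cov), 1.0):
            raise ValueError("covariance must have unit diagonal")
        off = cov[~np.eye(n, dtype=bool)]
        if np.any(np.abs(off) >= 1.0):
            raise ValueError("off-diagonal magnitudes must be < 1")
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(
            self, "module_assignment", np.asarray(self.module_assignment, int)
        )
        object.__setattr__(self, "hub_nodes", tuple(int(h) for h in self.hub_nodes))

    @property
    def n_nodes(self) -> int:
        return self.covariance.shape[0]


@dataclass(frozen=True)
class EffectSpec:
    """Planted post-session stimulation effect for one group.

    ``connectivity_attenuation`` multiplies the target node's
    off-diagonal covariance; ``amplitude_attenuation`` multiplies its
    signal scale.  Factors of 1 mean no effect (required for SHAM).
    """

    group: str
    target_node: int | None  # 0-based node index; None for SHAM
    connectivity_attenuation: float = 1.0
    amplitude_attenuation: float = 1.0

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for f in (self.connectivity_attenuation, self.amplitude_attenuation):
            if not 0.0 <= f <= 1.0:
                raise ValueError("attenuation factors must lie in [0, 1]")
        if self.group == "SHAM" and (
            self.connectivity_attenuation != 1.0
            or self.amplitude_attenuation != 1.0
        ):
            raise ValueError("SHAM effect must be the identity")

    def with_responsiveness(self, exponent: float) -> "EffectSpec":
        """Subject-specific effect: attenuations raised to ``exponent``.

        Exponents > 1 mean a stronger-than-average responder.  Shared
        between the connectivity and amplitude channels, which induces
        a positive across-subject correlation between the two changes.
        """
        return EffectSpec(
            group=self.group,
            target_node=self.target_node,
            connectivity_attenuation=self.connectivity_attenuation**exponent,
            amplitude_attenuation=self.amplitude_attenuation**exponent,
        )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation parameters (defaults mirror the study
    design: 3 x 15 subjects, 240 volumes at TR = 2 s, 0.01-0.08 Hz)."""

    n_per_group: int = 15
    n_volumes: int = 240
    tr_seconds: float = 2.0
    passband: tuple[float, float] = (0.01, 0.08)
    noise_sd: float = 0.4
    response_jitter: float = 0.5  # half-width of the responsiveness exponent
    seed: int = 0

    def __post_init__(self):
        nyq = 0.5 / self.tr_seconds
        low, high = self.passband
        if not (0 < low < high < nyq):
            raise ValueError("passband must lie within (0, Nyquist)")
        if self.n_volumes < 32:
            raise ValueError("n_volumes too small for spectral shaping")
        if not 0.0 <= self.response_jitter < 1.0:
            raise ValueError("response_jitter must be in [0, 1)")


def build_ground_truth(
    n_nodes: int = 29,
    modules: np.ndarray | list[int] | None = None,
    within_r: float = 0.45,
    between_r: float = 0.25,
    hub_spec: dict[int, float] | None = None,
) -> GroundTruthNetwork:
    """Block-structured correlation matrix with optional hub coupling.

    ``modules`` is a per-node community assignment (defaults to the
    atlas-derived medial/left/right partition).  ``hub_spec`` maps node
    index -> cross-module correlation floor for that node.  The matrix
    is repaired to the nearest positive-semidefinite matrix by
    eigenvalue clipping if the hub bumps break PSD-ness.
    """
    if not 0.0 <= between_r <= within_r < 1.0 or (
        between_r == within_r and within_r > 0
    ):
        raise ValueError("need 0 <= between_r < within_r < 1 (or both zero)")
    if modules is None:
        if n_nodes != 29:
            raise ValueError("default module partition requires 29 nodes")
        modules = default_modules()
    modules = np.asarray(modules, int)
    if modules.size != n_nodes:
        raise ValueError("module assignment length must equal n_nodes")
    same = modules[:, None] == modules[None, :]
    cov = np.where(same, within_r, between_r).astype(float)
    hub_spec = dict(hub_spec or {})
    for node, r in hub_spec.items():
        if not 0.0 <= r < 1.0:
            raise ValueError("hub coupling must be in [0, 1)")
        cross = ~same[node]
        cov[node, cross] = np.maximum(cov[node, cross], r)
        cov[cross, node] = cov[node, cross]
    np.fill_diagonal(cov, 1.0)

    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-10:
        vals, vecs = np.linalg.eigh(cov)
        vals = np.clip(vals, 1e-8, None)
        cov = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        cov = 0.5 * (cov + cov.T)
        np.fill_diagonal(cov, 1.0)
        logger.info("ground-truth covariance repaired to nearest PSD")
        if np.linalg.eigvalsh(cov).min() < -1e-8:
            raise np.linalg.LinAlgError(
                "covariance not positive semidefinite after repair"
            )
    return GroundTruthNetwork(cov, modules, tuple(sorted(hub_spec)))


def default_ground_truth() -> GroundTruthNetwork:
    """The cohort's default 29-node, 3-community, 4-hub structure.

    Hubs: the two stimulation targets (left paracentral lobule, right
    SMA) plus one lateral hub per hemisphere (left and right precentral/
    postcentral peaks), all with cross-module coupling 0.35.
    """
    hubs = {
        LEFT_PCL_ROI - 1: 0.35,
        RIGHT_SMA_ROI - 1: 0.35,
        11: 0.35,  # ROI 12, left postcentral gyrus
        16: 0.35,  # ROI 17, right precentral gyrus
    }
    return build_ground_truth(hub_spec=hubs)


def default_effects(
    connectivity_attenuation: float = 0.5,
    amplitude_attenuation: float = 0.7,
) -> dict[str, EffectSpec]:
    """Planted effects: LF hits the left-PCL analog, HF the right-SMA
    analog, SHAM nothing.  Both active groups share the same default
    attenuation factors."""
    return {
        "LF": EffectSpec(
            "LF", LEFT_PCL_ROI - 1, connectivity_attenuation, amplitude_attenuation
        ),
        "HF": EffectSpec(
            "HF", RIGHT_SMA_ROI - 1, connectivity_attenuation, amplitude_attenuation
        ),
        "SHAM": EffectSpec("SHAM", None),
    }


def session_covariance(
    gt: GroundTruthNetwork, effect: EffectSpec | None, session: str
) -> tuple[np.ndarray, np.ndarray]:
    """(covariance, per-node scale) actually sampled for a session."""
    cov = gt.covariance.copy()
    scale = np.ones(gt.n_nodes)
    if session == "post" and effect is not None and effect.target_node is not None:
        t = effect.target_node
        a = effect.connectivity_attenuation
        cov[t, :] *= a
        cov[:, t] *= a
        cov[t, t] = 1.0
        scale[t] = effect.amplitude_attenuation
        if np.linalg.eigvalsh(cov).min() < -1e-8:
            raise np.linalg.LinAlgError("attenuated covariance not PSD")
    return cov, scale


def _rng(*seeds) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seeds[0], spawn_key=seeds[1:]))


def simulate_session(
    gt: GroundTruthNetwork,
    effect: EffectSpec | None,
    session: str,
    cfg: CohortConfig,
    subject_seed: tuple[int, ...] | int,
    subject_id: str = "sub",
    group: str | None = None,
) -> SubjectSession:
    """Sample one session's (n_volumes x n_nodes) BOLD-like matrix.

    Deterministic given ``(cfg.seed, subject_seed)``; the effect is
    applied only when ``session == 'post'``.
    """
    if session not in SESSIONS:
        raise ValueError(f"unknown session {session!r}")
    cov, scale = session_covariance(gt, effect, session)
    if isinstance(subject_seed, int):
        subject_seed = (subject_seed,)
    rng = _rng(cfg.seed, *subject_seed, SESSIONS.index(session))

    # colour white noise, shape it into the analysis band, unit-scale
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(gt.n_nodes))
    white = rng.standard_normal((cfg.n_volumes, gt.n_nodes))
    x = white @ L.T
    x = bandpass(x, *cfg.passband, tr_seconds=cfg.tr_seconds)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    x = x / sd * scale
    x = x + cfg.noise_sd * rng.standard_normal(x.shape)
    return SubjectSession(
        subject_id=subject_id,
        group=group or (effect.group if effect is not None else "SHAM"),
        session=session,
        data=x,
        tr_seconds=cfg.tr_seconds,
    )


def simulate_voxel_rois(
    session: SubjectSession,
    voxels_per_roi: int = 20,
    gm_prob_range: tuple[float, float] = (0.3, 1.0),
    voxel_noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Explode ROI series into voxel series with grey-matter weights.

    Each ROI's voxels are the ROI signal plus independent voxel noise;
    the returned weight table has columns (voxel, roi, weight).  A
    weighted mean of each ROI's voxels recovers the ROI series up to
    the voxel noise.
    """
    if voxels_per_roi < 1:
        raise ValueError("voxels_per_roi must be >= 1")
    rng = _rng(seed)
    t, n = session.data.shape
    voxels = np.repeat(session.data, voxels_per_roi, axis=1)
    voxels = voxels + voxel_noise_sd * rng.standard_normal(voxels.shape)
    lo, hi = gm_prob_range
    weights = pd.DataFrame(
        {
            "voxel": np.arange(n * voxels_per_roi),
            "roi": np.repeat(np.arange(n), voxels_per_roi),
            "weight": rng.uniform(lo, hi, n * voxels_per_roi),
        }
    )
    return voxels, weights


def simulate_nuisance(
    cfg: CohortConfig,
    seed: tuple[int, ...] | int = 0,
    motion_step_sd: float = 0.02,
) -> NuisanceSet:
    """Smooth random-walk motion traces plus WM/CSF signals.

    The 6 motion parameters are Gaussian random walks whose first
    differences have standard deviation ``motion_step_sd``.  WM and CSF
    share a common low-frequency physiological component, making them
    partially correlated with each other (and with any global signal
    built from them)."""
    if isinstance(seed, int):
        seed = (seed,)
    rng = _rng(cfg.seed, *seed, 999)
    t = cfg.n_volumes
    motion = np.cumsum(
        motion_step_sd * rng.standard_normal((t, 6)), axis=0
    )
    physio = bandpass(
        rng.standard_normal(t), *cfg.passband, tr_seconds=cfg.tr_seconds
    )
    physio = physio / max(physio.std(), 1e-12)
    wm = 0.6 * physio + 0.8 * rng.standard_normal(t)
    csf = 0.6 * physio + 0.8 * rng.standard_normal(t)
    return NuisanceSet(motion, wm, csf)


@dataclass
class Cohort:
    """A fully simulated cohort plus its generating ground truth."""

    sessions: list[SubjectSession]
    nuisance: dict[tuple[str, str], NuisanceSet]
    ground_truth: GroundTruthNetwork
    effects: dict[str, EffectSpec]
    subject_effects: dict[str, EffectSpec]
    config: CohortConfig
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)


def generate_cohort(
    cfg: CohortConfig | None = None,
    gt: GroundTruthNetwork | None = None,
    effects: dict[str, EffectSpec] | None = None,
    groups: tuple[str, ...] = GROUPS,
    with_nuisance: bool = True,
) -> Cohort:
    """Simulate the full cohort: ``groups x n_per_group x {pre, post}``.

    Subject seeds are derived from the cohort seed via a counter-based
    spawn-key scheme, so subjects are independent and the whole cohort
    is bit-reproducible from ``cfg.seed`` alone.
    """
    cfg = cfg or CohortConfig()
    gt = gt or default_ground_truth()
    effects = effects or default_effects()
    sessions: list[SubjectSession] = []
    nuisance: dict[tuple[str, str], NuisanceSet] = {}
    subject_effects: dict[str, EffectSpec] = {}
    rows = []
    for gi, group in enumerate(groups):
        base = effects[group]
        for s in range(cfg.n_per_group):
            sid = f"{group}{s + 1:02d}"
            rng = _rng(cfg.seed, gi, s, 7)
            exponent = 1.0 + cfg.response_jitter * (2 * rng.random() - 1)
            eff = base.with_responsiveness(exponent)
            subject_effects[sid] = eff
            for session in SESSIONS:
                sess = simulate_session(
                    gt, eff, session, cfg, (gi, s), subject_id=sid, group=group
                )
                sessions.append(sess)
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "session": session,
                        "seed": f"{cfg.seed}:{gi}:{s}",
                    }
                )
            if with_nuisance:
                for session in SESSIONS:
                    nuisance[(sid, session)] = simulate_nuisance(
                        cfg, (gi, s, SESSIONS.index(session))
                    )
    return Cohort(
        sessions=sessions,
        nuisance=nuisance,
        ground_truth=gt,
        effects=effects,
        subject_effects=subject_effects,
        config=cfg,
        manifest=pd.DataFrame(rows),
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write TSV series per subject-session, a CSV manifest and a
    ground-truth JSON into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = roi_labels(load_atlas()) if cohort.ground_truth.n_nodes == 29 else [
        f"node{i:02d}" for i in range(cohort.ground_truth.n_nodes)
    ]
    paths = []
    for sess in cohort.sessions:
        fname = f"{sess.subject_id}_{sess.session}.tsv"
        pd.DataFrame(sess.data, columns=labels).to_csv(
            out / fname, sep="\t", index=False, float_format="%.6f"
        )
        paths.append(fname)
    manifest = cohort.manifest.copy()
    manifest["path"] = paths
    manifest.to_csv(out / "manifest.csv", index=False)
    for (sid, session), nuis in cohort.nuisance.items():
        df = pd.DataFrame(
            nuis.motion6, columns=[f"mot{i}" for i in range(1, 7)]
        )
        df["wm"] = nuis.wm
        df["csf"] = nuis.csf
        df.to_csv(out / f"{sid}_{session}_nuisance.csv", index=False)
    gt_payload = {
        "covariance": cohort.ground_truth.covariance.tolist(),
        "module_assignment": cohort.ground_truth.module_assignment.tolist(),
        "hub_nodes": list(cohort.ground_truth.hub_nodes),
        "effects": {
            g: {
                "target_node": e.target_node,
                "connectivity_attenuation": e.connectivity_attenuation,
                "amplitude_attenuation": e.amplitude_attenuation,
            }
            for g, e in cohort.effects.items()
        },
        "config": {
            "n_per_group": cohort.config.n_per_group,
            "n_volumes": cohort.config.n_volumes,
            "tr_seconds": cohort.config.tr_seconds,
            "passband": list(cohort.config.passband),
            "noise_sd": cohort.config.noise_sd,
            "response_jitter": cohort.config.response_jitter,
            "seed": cohort.config.seed,
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(gt_payload, indent=1))
    return out


def read_session(path: str | Path, subject_id, group, session, tr_seconds=2.0):
    """Load one subject-session TSV back into a :class:`SubjectSession`."""
    df = pd.read_csv(path, sep="\t")
    if df.isna().any().any():
        bad = int(np.where(df.isna().any(axis=1))[0][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: missing value at line {bad}")
    return SubjectSession(subject_id, group, session, df.to_numpy(float), tr_seconds)
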