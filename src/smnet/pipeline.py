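"""End-to-end orchestration: simulate -> preprocess -> network ->
metrics -> activity/FC -> group statistics.

Every stage is a pure function over in-memory objects so tests and
scripts can run any slice of the pipeline; :func:`run_all` wires them
together, writes tidy CSV outputs and a provenance report, and is
bit-reproducible from the master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity, metrics, netbuild, stats
from .atlas import load_atlas, roi_labels
from .cohort import (
    Cohort,
    CohortConfig,
    default_effects,
    default_ground_truth,
    generate_cohort,
)
from .preprocess import preprocess_session

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated, serialisable configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    connectivity_attenuation: float = 0.5
    amplitude_attenuation: float = 0.7
    n_discard: int = 5
    sparsity_low: float = 0.04
    sparsity_high: float = 0.40
    sparsity_step: float = 0.02
    n_null: int = 100
    alpha: float = 0.05
    nodal_family_size: int = 29
    posthoc_family_size: int = 9
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)
        # one master seed drives everything
        if self.cohort.seed != self.seed:
            object.__setattr__(self, "cohort", CohortConfig(
                **{**asdict(self.cohort), "seed": self.seed}
            ))
        netbuild.sparsity_grid(self.sparsity_low, self.sparsity_high, self.sparsity_step)
        if self.n_null < 0 or not 0 < self.alpha < 1:
            raise ValueError("invalid n_null or alpha")

    @property
    def grid(self) -> np.ndarray:
        return netbuild.sparsity_grid(
            self.sparsity_low, self.sparsity_high, self.sparsity_step
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["cohort"]["passband"] = list(payload["cohort"]["passband"])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


NODAL_METRICS = ("degree", "betweenness", "nodal_eff")
GLOBAL_METRICS = ("e_glob", "e_loc")


def preprocess_cohort(cohort: Cohort, n_discard: int = 5) -> list:
    """Run the temporal pipeline on every session of the cohort."""
    low, high = cohort.config.passband
    out = []
    for sess in cohort.sessions:
        nuis = cohort.nuisance.get((sess.subject_id, sess.session))
        out.append(preprocess_session(sess, nuis, n_discard, low, high))
    return out


def session_metrics(
    sess,
    grid: np.ndarray,
    n_null: int = 0,
    seed: int | np.random.Generator = 0,
    labels=None,
) -> metrics.MetricCurveSet:
    """Correlation matrix -> thresholded metric curves for one session."""
    C = netbuild.correlation_matrix(sess.data, labels)
    return metrics.curves_and_auc(C, grid, n_null=n_null, seed=seed)


def metrics_table(
    sessions: list,
    grid: np.ndarray,
    n_null: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy per-session AUC table.

    Columns: subject, group, session, metric, node (empty for global
    metrics), auc; plus normalised-efficiency grid means when
    ``n_null > 0`` (used for small-world classification).
    """
    rows = []
    for k, sess in enumerate(sessions):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        cs = session_metrics(sess, grid, n_null=n_null, seed=rng)
        base = {
            "subject": sess.subject_id,
            "group": sess.group,
            "session": sess.session,
        }
        for m in GLOBAL_METRICS:
            rows.append({**base, "metric": m, "node": -1, "auc": cs.auc[m]})
        if n_null:
            rows.append(
                {
                    **base,
                    "metric": "e_glob_norm_mean",
                    "node": -1,
                    "auc": float(np.mean(cs.e_glob_norm)),
                }
            )
            rows.append(
                {
                    **base,
                    "metric": "e_loc_norm_mean",
                    "node": -1,
                    "auc": float(np.mean(cs.e_loc_norm)),
                }
            )
        for m in NODAL_METRICS:
            for node, v in enumerate(cs.auc[m]):
                rows.append({**base, "metric": m, "node": node, "auc": float(v)})
    return pd.DataFrame(rows)


def activity_table(sessions: list, band=(0.01, 0.08)) -> pd.DataFrame:
    """Per-session, per-node ALFF in tidy form."""
    rows = []
    for sess in sessions:
        vals = activity.alff_all_nodes(sess.data, sess.tr_seconds, band)
        for node, v in enumerate(vals):
            rows.append(
                {
                    "subject": sess.subject_id,
                    "group": sess.group,
                    "session": sess.session,
                    "node": node,
                    "alff": float(v),
                }
            )
    return pd.DataFrame(rows)


def fc_table(sessions: list, seed_nodes: list[int]) -> pd.DataFrame:
    """Fisher-z FC from each seed node to all others, per session."""
    rows = []
    for sess in sessions:
        for seed_node in seed_nodes:
            z = activity.fc_vector(sess.data, seed_node)
            for node, v in enumerate(z):
                if node == seed_node:
                    continue
                rows.append(
                    {
                        "subject": sess.subject_id,
                        "group": sess.group,
                        "session": sess.session,
                        "seed": seed_node,
                        "target": node,
                        "z": float(v),
                    }
                )
    return pd.DataFrame(rows)


def anova_tables(
    mtab: pd.DataFrame,
    alpha: float = 0.05,
    nodal_family_size: int = 29,
    posthoc_family_size: int = 9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mixed ANOVA per response, Bonferroni per metric family, post-hoc
    contrasts where the interaction survives correction.

    Returns (anova table, post-hoc table).  Nodal metrics form a
    29-node Bonferroni family per metric; each global metric its own
    family of 1.
    """
    anova_rows = []
    posthoc_rows = []
    for metric, mdf in mtab.groupby("metric"):
        nodes = sorted(mdf["node"].unique())
        fam = nodal_family_size if metric in NODAL_METRICS else 1
        node_results = {}
        for node in nodes:
            ndf = mdf[mdf["node"] == node].rename(columns={"auc": "value"})
            res = stats.mixed_anova(ndf)
            node_results[node] = (res, ndf)
            anova_rows.append(
                {
                    "metric": metric,
                    "node": node,
                    "F_group": res.f_group,
                    "p_group": res.p_group,
                    "F_session": res.f_session,
                    "p_session": res.p_session,
                    "F_interaction": res.f_interaction,
                    "df1": res.df_interaction[0],
                    "df2": res.df_interaction[1],
                    "p_interaction": res.p_interaction,
                    "p_interaction_bonf": min(1.0, res.p_interaction * fam),
                    "family_size": fam,
                }
            )
        for node, (res, ndf) in node_results.items():
            if min(1.0, res.p_interaction * fam) < alpha:
                for rec in stats.posthoc_sessions(
                    ndf, family_size=posthoc_family_size
                ):
                    posthoc_rows.append(
                        {
                            "metric": metric,
                            "node": node,
                            "contrast": rec.contrast,
                            "t": rec.statistic,
                            "df": rec.df,
                            "p_raw": rec.p_raw,
                            "p_bonf": rec.p_corrected,
                            "family_size": rec.family_size,
                        }
                    )
    return pd.DataFrame(anova_rows), pd.DataFrame(posthoc_rows)


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline and write all outputs to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    t0 = time.time()

    logger.info("stage simulate")
    effects = default_effects(
        config.connectivity_attenuation, config.amplitude_attenuation
    )
    cohort = generate_cohort(config.cohort, default_ground_truth(), effects)
    from .cohort import write_cohort

    write_cohort(cohort, out / "cohort")

    logger.info("stage preprocess")
    sessions = preprocess_cohort(cohort, config.n_discard)

    logger.info("stage network+metrics")
    labels = tuple(roi_labels(load_atlas()))
    mtab = metrics_table(sessions, config.grid, n_null=config.n_null, seed=config.seed)
    mtab.to_csv(out / "metrics_auc.csv", index=False)

    logger.info("stage activity")
    atab = activity_table(sessions, cohort.config.passband)
    atab.to_csv(out / "alff.csv", index=False)

    logger.info("stage statistics")
    anova, posthoc = anova_tables(
        mtab[mtab["metric"].isin(NODAL_METRICS + GLOBAL_METRICS)],
        alpha=config.alpha,
        nodal_family_size=config.nodal_family_size,
        posthoc_family_size=config.posthoc_family_size,
    )
    anova.to_csv(out / "anova.csv", index=False)
    posthoc.to_csv(out / "posthoc.csv", index=False)

    sig = anova[
        (anova["metric"].isin(NODAL_METRICS))
        & (anova["p_interaction_bonf"] < config.alpha)
    ]
    seed_nodes = sorted(sig["node"].unique())
    if seed_nodes:
        ftab = fc_table(sessions, seed_nodes)
        ftab.to_csv(out / "fc_z.csv", index=False)

    # Table-2-shaped summary: significant interactions + best post-hoc
    table2_rows = []
    for _, row in sig.iterrows():
        sub = posthoc[
            (posthoc["metric"] == row["metric"]) & (posthoc["node"] == row["node"])
        ]
        within = sub[sub["contrast"].str.contains("pre vs post")]
        best = within.loc[within["p_bonf"].idxmin()] if len(within) else None
        table2_rows.append(
            {
                "metric": row["metric"],
                "region": labels[int(row["node"])],
                "F": row["F_interaction"],
                "p": row["p_interaction"],
                "posthoc": None if best is None else best["contrast"],
                "posthoc_p": None if best is None else best["p_bonf"],
            }
        )
    pd.DataFrame(
        table2_rows, columns=["metric", "region", "F", "p", "posthoc", "posthoc_p"]
    ).to_csv(out / "significant_interactions.csv", index=False)

    report = {
        "seed": config.seed,
        "n_sessions": len(sessions),
        "grid": config.grid.tolist(),
        "n_null": config.n_null,
        "alpha": config.alpha,
        "nodal_family_size": config.nodal_family_size,
        "posthoc_family_size": config.posthoc_family_size,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=1))
    return out
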