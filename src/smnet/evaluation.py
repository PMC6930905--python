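"""Validation studies over the synthetic cohort.

These functions re-run the full method on freshly simulated data and
summarise how well it behaves: demographic statistics of the study
cohort, small-world classification rates, recovery of the planted
low-frequency-stimulation effect, and the empirical size of the
group x session interaction test under the null.  They are the engine
behind ``scripts/acceptance.py`` and the heavier end of the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .activity import alff
from .atlas import LEFT_PCL_ROI
from .cohort import (
    CohortConfig,
    EffectSpec,
    default_effects,
    default_ground_truth,
    generate_cohort,
)
from .metrics import classify_small_world, curves_and_auc
from .netbuild import correlation_matrix, degree_sparsity_curve, sparsity_grid
from .pipeline import preprocess_cohort
from .stats import (
    chi_square_independence,
    mixed_anova,
    one_way_anova_from_summary,
    paired_ttest,
    pearson_r,
)

# Demographic summaries of the study cohort (3 groups of 15):
# per-group age mean/sd in years, scan-interval mean/sd in minutes,
# and the female/male split.  These are the inputs to the demographic
# homogeneity checks.
AGE_SUMMARY = {"means": (24.0, 22.8, 22.4), "sds": (2.56, 3.10, 2.16), "ns": (15, 15, 15)}
INTERVAL_SUMMARY = {
    "means": (13.93, 14.67, 12.40),
    "sds": (4.30, 5.01, 5.18),
    "ns": (15, 15, 15),
}
SEX_TABLE = ((7, 7, 6), (8, 8, 9))


def demographic_checks() -> dict:
    """One-way ANOVAs (age, scan interval) and the sex chi-square."""
    age = one_way_anova_from_summary(**AGE_SUMMARY)
    interval = one_way_anova_from_summary(**INTERVAL_SUMMARY)
    chi2, df, p = chi_square_independence(SEX_TABLE)
    return {
        "age": {"F": age[0], "df": (age[1], age[2]), "p": age[3]},
        "interval": {"F": interval[0], "df": (interval[1], interval[2]), "p": interval[3]},
        "sex": {"chi2": chi2, "df": df, "p": p},
    }


def small_world_study(
    seed: int = 0,
    n_per_group: int = 15,
    n_null: int = 20,
    glob_tol: float = 0.15,
) -> dict:
    """Small-world classification of every subject-session network.

    Simulates the default cohort, preprocesses it, thresholds each
    network over the sparsity grid and normalises the efficiencies
    against ``n_null`` degree-preserving nulls per threshold.  Returns
    the fraction of sessions classified small-world together with the
    grid-mean normalised efficiencies.
    """
    cohort = generate_cohort(CohortConfig(n_per_group=n_per_group, seed=seed))
    sessions = preprocess_cohort(cohort)
    grid = sparsity_grid()
    flags, eg, el = [], [], []
    for k, sess in enumerate(sessions):
        C = correlation_matrix(sess.data)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, k)))
        cs = curves_and_auc(C, grid, n_null=n_null, seed=rng)
        flags.append(classify_small_world(cs, glob_tol))
        eg.append(float(np.nanmean(cs.e_glob_norm)))
        el.append(float(np.nanmean(cs.e_loc_norm)))
    return {
        "fraction_small_world": float(np.mean(flags)),
        "mean_e_glob_norm": float(np.mean(eg)),
        "mean_e_loc_norm": float(np.mean(el)),
        "n_sessions": len(sessions),
    }


def lf_effect_recovery_study(
    n_cohorts: int = 25,
    seed: int = 0,
    n_per_group: int = 15,
) -> dict:
    """Recovery of the planted low-frequency-rTMS effect.

    For each simulated cohort the LF group's sessions are run through
    the full pipeline; per node, a paired pre-vs-post t-test on the
    degree and betweenness AUCs forms the 29-contrast post-hoc family.
    Reports how often the planted left-PCL analog attains the family's
    minimum p, and the across-subject correlation between its degree-AUC
    change and its ALFF change.
    """
    target = LEFT_PCL_ROI - 1
    grid = sparsity_grid()
    gt = default_ground_truth()
    effects = default_effects()
    deg_wins = bc_wins = 0
    corrs = []
    for c in range(n_cohorts):
        cfg = CohortConfig(n_per_group=n_per_group, seed=seed * 100_003 + c)
        cohort = generate_cohort(cfg, gt, effects, groups=("LF",))
        sessions = preprocess_cohort(cohort)
        per = {}
        for s in sessions:
            C = correlation_matrix(s.data)
            cs = curves_and_auc(C, grid)
            per[(s.subject_id, s.session)] = (
                cs.auc["degree"],
                cs.auc["betweenness"],
                alff(s.data[:, target], s.tr_seconds),
            )
        sids = sorted({k[0] for k in per})
        deg_p, bc_p = [], []
        for node in range(29):
            pre_d = [per[(sid, "pre")][0][node] for sid in sids]
            post_d = [per[(sid, "post")][0][node] for sid in sids]
            pre_b = [per[(sid, "pre")][1][node] for sid in sids]
            post_b = [per[(sid, "post")][1][node] for sid in sids]
            deg_p.append(paired_ttest(pre_d, post_d)[2])
            bc_p.append(paired_ttest(pre_b, post_b)[2])
        deg_wins += int(np.argmin(deg_p) == target)
        bc_wins += int(np.argmin(bc_p) == target)
        d_deg = [per[(sid, "post")][0][target] - per[(sid, "pre")][0][target] for sid in sids]
        d_alff = [per[(sid, "post")][2] - per[(sid, "pre")][2] for sid in sids]
        corrs.append(pearson_r(d_deg, d_alff)[0])
    return {
        "fraction_degree_family_min": deg_wins / n_cohorts,
        "fraction_betweenness_family_min": bc_wins / n_cohorts,
        "mean_alff_degree_change_corr": float(np.mean(corrs)),
        "fraction_positive_corr": float(np.mean(np.asarray(corrs) > 0)),
        "n_cohorts": n_cohorts,
    }


def interaction_type_i_error(
    n_reps: int = 1000,
    seed: int = 0,
    node: int = 0,
    n_per_group: int = 15,
    alpha: float = 0.05,
) -> dict:
    """Empirical size of the group x session interaction test.

    Each replicate simulates a no-effect cohort, computes one node's
    degree AUC per subject-session (via the nested-threshold fast path;
    the simulated series are already band-limited, so no further
    preprocessing is applied) and records whether the mixed-ANOVA
    interaction rejects at ``alpha``.
    """
    grid = sparsity_grid()
    gt = default_ground_truth()
    null_effects = {g: EffectSpec(g, None) for g in ("HF", "LF", "SHAM")}
    hits = 0
    for rep in range(n_reps):
        cfg = CohortConfig(n_per_group=n_per_group, seed=seed * 2_000_003 + rep)
        cohort = generate_cohort(cfg, gt, null_effects, with_nuisance=False)
        rows = []
        for s in cohort.sessions:
            C = correlation_matrix(s.data)
            degs = degree_sparsity_curve(C, grid)[:, node]
            rows.append(
                {
                    "subject": s.subject_id,
                    "group": s.group,
                    "session": s.session,
                    "value": float(np.trapezoid(degs, grid)),
                }
            )
        hits += mixed_anova(pd.DataFrame(rows)).p_interaction < alpha
    return {"empirical_alpha": hits / n_reps, "n_reps": n_reps, "nominal_alpha": alpha}


def planted_cohort_interactions(seed: int = 0, n_per_group: int = 15) -> pd.DataFrame:
    """Full-pipeline ANOVA table for one planted cohort (all groups).

    Returns the per-node interaction results for degree and betweenness
    AUC -- the synthetic analog of the study's significant-interaction
    table.
    """
    from .pipeline import anova_tables, metrics_table

    cohort = generate_cohort(CohortConfig(n_per_group=n_per_group, seed=seed))
    sessions = preprocess_cohort(cohort)
    mtab = metrics_table(sessions, sparsity_grid(), n_null=0, seed=seed)
    anova, posthoc = anova_tables(mtab)
    return anova, posthoc
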