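"""Group-level statistical inference.

Covers every inferential step of the analysis: one-way ANOVA from group
summaries (demographics), chi-square independence (sex ratio), the
two-way mixed-design (split-plot) ANOVA with a 3-level between factor
(group) and 2-level within factor (session), Bonferroni correction,
post-hoc paired/two-sample t-tests, and Pearson correlation of change
scores.

With two within-subject levels the mixed-model interaction F is
algebraically identical to a one-way ANOVA on per-subject (post - pre)
difference scores, and sphericity corrections are vacuous; none are
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats


def one_way_anova_from_summary(means, sds, ns) -> tuple[float, int, int, float]:
    """One-way ANOVA from per-group (mean, sd, n) summaries.

    Returns (F, df1, df2, p).  A zero within-group mean square with
    nonzero between-group variability yields F = inf.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    g = means.size
    if g < 2 or sds.size != g or ns.size != g:
        raise ValueError("need matching summaries for at least 2 groups")
    if np.any(ns < 2) or np.any(sds < 0):
        raise ValueError("each group needs n >= 2 and sd >= 0")
    n_tot = int(ns.sum())
    grand = float((ns * means).sum() / n_tot)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df1, df2 = g - 1, n_tot - g
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0:
        f = float("inf") if ms_between > 0 else 0.0
    else:
        f = ms_between / ms_within
    p = float(sp_stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return f, df1, df2, p


def chi_square_independence(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction.  Returns (chi2, df, p).
    """
    obs = np.asarray(counts, float)
    if obs.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row/column margin")
    expected = row @ col / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, df, float(sp_stats.chi2.sf(chi2, df))


@dataclass
class MixedAnovaResult:
    """F tests from the split-plot decomposition, plus the SS table."""

    f_group: float
    df_group: tuple[int, int]
    p_group: float
    f_session: float
    df_session: tuple[int, int]
    p_session: float
    f_interaction: float
    df_interaction: tuple[int, int]
    p_interaction: float
    ss: dict = field(default_factory=dict)


def mixed_anova(
    design: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    session: str = "session",
    subject: str = "subject",
) -> MixedAnovaResult:
    """Two-way mixed-design ANOVA (between: group, within: 2 sessions).

    ``design`` is long-format with one row per subject-session.  The
    classical split-plot decomposition is used:

    * group tested against subjects-within-groups,
    * session and group x session tested against the
      session x subjects-within-groups residual.
    """
    df = design[[subject, group, session, value]].copy()
    sess_levels = sorted(df[session].unique())
    if len(sess_levels) != 2:
        raise ValueError("exactly 2 within-subject levels required")
    counts = df.groupby(subject)[session].nunique()
    if (counts != 2).any():
        missing = counts[counts != 2].index.tolist()
        raise ValueError(f"subjects missing a session: {missing}")

    wide = df.pivot_table(index=[subject, group], columns=session, values=value)
    y = wide.to_numpy()  # subjects x 2
    groups = wide.index.get_level_values(group).to_numpy()
    labels, inv = np.unique(groups, return_inverse=True)
    g = labels.size
    n_j = np.bincount(inv)
    n_tot = int(n_j.sum())
    w = 2  # within levels

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[inv == j].mean() for j in range(g)])
    sess_means = y.mean(axis=0)
    cell_means = np.array([y[inv == j].mean(axis=0) for j in range(g)])  # g x 2

    ss_group = w * float((n_j * (group_means - grand) ** 2).sum())
    ss_subj = w * float(((subj_means - group_means[inv]) ** 2).sum())
    ss_session = n_tot * float(((sess_means - grand) ** 2).sum())
    ss_inter = float(
        (
            n_j[:, None]
            * (cell_means - group_means[:, None] - sess_means[None, :] + grand) ** 2
        ).sum()
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss_error = ss_total - ss_group - ss_subj - ss_session - ss_inter

    df_group = g - 1
    df_subj = n_tot - g
    df_session = w - 1
    df_inter = (g - 1) * (w - 1)
    df_error = (n_tot - g) * (w - 1)

    ms = {
        "group": ss_group / df_group,
        "subj": ss_subj / df_subj,
        "session": ss_session / df_session,
        "interaction": ss_inter / df_inter,
        "error": ss_error / df_error,
    }

    def ftest(ms_num, ms_den, df1, df2):
        if ms_den <= 0:
            f = float("inf") if ms_num > 0 else 0.0
        else:
            f = ms_num / ms_den
        p = float(sp_stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        return f, p

    f_g, p_g = ftest(ms["group"], ms["subj"], df_group, df_subj)
    f_s, p_s = ftest(ms["session"], ms["error"], df_session, df_error)
    f_i, p_i = ftest(ms["interaction"], ms["error"], df_inter, df_error)
    return MixedAnovaResult(
        f_group=f_g,
        df_group=(df_group, df_subj),
        p_group=p_g,
        f_session=f_s,
        df_session=(df_session, df_error),
        p_session=p_s,
        f_interaction=f_i,
        df_interaction=(df_inter, df_error),
        p_interaction=p_i,
        ss={
            "group": ss_group,
            "subjects_within_groups": ss_subj,
            "session": ss_session,
            "interaction": ss_inter,
            "session_x_subjects": ss_error,
            "total": ss_total,
        },
    )


def bonferroni(pvals, alpha: float = 0.05, m: int | None = None):
    """Bonferroni correction: corrected p = min(1, p * m).

    Returns (corrected p array, boolean significance flags).  ``m``
    defaults to the number of p-values supplied.
    """
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    corrected = np.minimum(1.0, p * m)
    return corrected, corrected < alpha


def paired_ttest(x, y) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p).

    Identical pairs give t = 0, p = 1; zero-variance nonzero
    differences are flagged with an infinite t and p = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    d = x - y
    df = d.size - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    res = sp_stats.ttest_rel(x, y)
    return float(res.statistic), df, float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    res = sp_stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PosthocRecord:
    """One post-hoc contrast with its raw and Bonferroni-corrected p."""

    contrast: str
    statistic: float
    df: int
    p_raw: float
    p_corrected: float
    family_size: int

    @property
    def significant(self) -> bool:
        return self.p_corrected < 0.05


def posthoc_sessions(
    design: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    session: str = "session",
    subject: str = "subject",
    family_size: int | None = None,
) -> list[PosthocRecord]:
    """Post-hoc contrasts for a response with a significant interaction.

    Within each group, a paired two-sided t-test pre vs post; between
    each pair of groups at each session, a two-sample t-test.  All
    contrasts are Bonferroni-corrected within the post-hoc family
    (default family size: the 3 + 6 = 9 contrasts actually run).
    """
    wide = design.pivot_table(index=[subject, group], columns=session, values=value)
    groups = sorted(wide.index.get_level_values(group).unique())
    records: list[tuple[str, float, int, float]] = []
    for gname in groups:
        sub = wide.xs(gname, level=group)
        t, df, p = paired_ttest(sub["pre"].to_numpy(), sub["post"].to_numpy())
        records.append((f"{gname}: pre vs post", t, df, p))
    for sess in ("pre", "post"):
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a = wide.xs(groups[i], level=group)[sess].to_numpy()
                b = wide.xs(groups[j], level=group)[sess].to_numpy()
                res = sp_stats.ttest_ind(a, b)
                records.append(
                    (
                        f"{groups[i]} vs {groups[j]} at {sess}",
                        float(res.statistic),
                        a.size + b.size - 2,
                        float(res.pvalue),
                    )
                )
    m = family_size if family_size is not None else len(records)
    out = []
    for contrast, t, df, p in records:
        out.append(
            PosthocRecord(
                contrast=contrast,
                statistic=t,
                df=df,
                p_raw=p,
                p_corrected=min(1.0, p * m),
                family_size=m,
            )
        )
    return out
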