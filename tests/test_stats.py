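"""Statistical engine: summary ANOVA, chi-square, mixed ANOVA,
corrections, post-hoc and correlation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

import pingouin as pg

from smnet import (
    bonferroni,
    chi_square_independence,
    mixed_anova,
    one_way_anova_from_summary,
    paired_ttest,
    pearson_r,
    posthoc_sessions,
)


def make_design(rng, n_per_group=15, group_shift=(0, 0, 0), session_shift=(0, 0, 0), sd=1.0):
    rows = []
    for gi, g in enumerate(["HF", "LF", "SHAM"]):
        for s in range(n_per_group):
            base = rng.normal(scale=sd)
            for si, sess in enumerate(["pre", "post"]):
                rows.append(
                    {
                        "subject": f"{g}{s:02d}",
                        "group": g,
                        "session": sess,
                        "value": base
                        + rng.normal(scale=sd)
                        + group_shift[gi]
                        + si * session_shift[gi],
                    }
                )
    return pd.DataFrame(rows)


class TestSummaryAnova:
    def test_age_summaries(self):
        f, df1, df2, p = one_way_anova_from_summary(
            [24, 22.8, 22.4], [2.56, 3.10, 2.16], [15, 15, 15]
        )
        assert (df1, df2) == (2, 42)
        assert f == pytest.approx(1.496, abs=0.005)
        assert p == pytest.approx(0.236, abs=0.002)

    def test_interval_summaries(self):
        f, *_ , p = one_way_anova_from_summary(
            [13.93, 14.67, 12.40], [4.30, 5.01, 5.18], [15, 15, 15]
        )
        assert f == pytest.approx(0.855, abs=0.005)
        assert p == pytest.approx(0.433, abs=0.002)

    def test_identical_means_give_zero_f(self):
        f, *_ = one_way_anova_from_summary([5, 5, 5], [1, 2, 1], [10, 10, 10])
        assert f == 0.0

    def test_matches_scipy_on_raw_data(self, rng):
        groups = [rng.normal(loc=i, size=12) for i in range(3)]
        f_ref = sp_stats.f_oneway(*groups)
        f, _, _, p = one_way_anova_from_summary(
            [g.mean() for g in groups],
            [g.std(ddof=1) for g in groups],
            [len(g) for g in groups],
        )
        assert f == pytest.approx(f_ref.statistic)
        assert p == pytest.approx(f_ref.pvalue)


class TestChiSquare:
    def test_sex_table(self):
        chi2, df, p = chi_square_independence([[7, 7, 6], [8, 8, 9]])
        assert chi2 == pytest.approx(0.18, abs=0.005)
        assert df == 2
        assert p == pytest.approx(0.914, abs=0.002)

    def test_independent_columns_zero(self):
        chi2, _, p = chi_square_independence([[5, 5], [8, 8]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_value(self):
        chi2, df, _ = chi_square_independence([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [1, 2]])


class TestMixedAnova:
    def test_matches_pingouin(self, rng):
        df = make_design(rng, group_shift=(0, 0.4, 0.8), session_shift=(0, 0.3, 0.6))
        res = mixed_anova(df)
        ref = pg.mixed_anova(
            data=df, dv="value", within="session", subject="subject", between="group"
        ).set_index("Source")
        assert res.f_group == pytest.approx(ref.loc["group", "F"])
        assert res.f_session == pytest.approx(ref.loc["session", "F"])
        assert res.f_interaction == pytest.approx(ref.loc["Interaction", "F"])
        assert res.p_interaction == pytest.approx(ref.loc["Interaction", "p_unc"])
        assert res.df_interaction == (2, 42)

    def test_interaction_equals_anova_on_difference_scores(self, rng):
        for _ in range(5):
            df = make_design(rng, session_shift=tuple(rng.normal(size=3)))
            res = mixed_anova(df)
            wide = df.pivot_table(index=["subject", "group"], columns="session", values="value")
            diffs = (wide["post"] - wide["pre"]).reset_index()
            groups = [
                diffs[diffs["group"] == g][0].to_numpy() for g in ("HF", "LF", "SHAM")
            ]
            ref = sp_stats.f_oneway(*groups)
            assert abs(res.f_interaction - ref.statistic) < 1e-8

    def test_equal_difference_means_give_zero_interaction(self):
        rows = []
        for g in ("HF", "LF", "SHAM"):
            for s, d in enumerate((1.0, -1.0)):
                rows.append({"subject": f"{g}{s}", "group": g, "session": "pre", "value": 0.0})
                rows.append({"subject": f"{g}{s}", "group": g, "session": "post", "value": d})
        res = mixed_anova(pd.DataFrame(rows))
        assert res.f_interaction == pytest.approx(0.0, abs=1e-12)

    def test_ss_decomposition_adds_up(self, rng):
        df = make_design(rng, group_shift=(0, 1, 2), session_shift=(0.5, 0, 0.2))
        res = mixed_anova(df)
        parts = (
            res.ss["group"]
            + res.ss["subjects_within_groups"]
            + res.ss["session"]
            + res.ss["interaction"]
            + res.ss["session_x_subjects"]
        )
        assert parts == pytest.approx(res.ss["total"], abs=1e-8)

    def test_missing_session_rejected(self, rng):
        df = make_design(rng).iloc[1:]
        with pytest.raises(ValueError, match="missing"):
            mixed_anova(df)

    def test_gaussian_null_type_one_error(self, rng):
        """Under an exchangeable Gaussian null, the interaction test
        rejects at close to the nominal 5% rate."""
        hits = 0
        n = 400
        for _ in range(n):
            df = make_design(rng, n_per_group=8)
            hits += mixed_anova(df).p_interaction < 0.05
        assert hits / n == pytest.approx(0.05, abs=0.025)


class TestBonferroni:
    def test_family_of_one_unchanged(self):
        corrected, flags = bonferroni([0.03])
        assert corrected[0] == 0.03 and flags[0]

    def test_m29_arithmetic(self):
        corrected, flags = bonferroni([0.01], m=29)
        assert corrected[0] == pytest.approx(0.29)
        assert not flags[0]

    def test_monotone_flags(self, rng):
        p = np.sort(rng.uniform(size=10))
        _, flags = bonferroni(p, m=10)
        # once non-significant, larger p never significant again
        assert np.all(np.diff(flags.astype(int)) <= 0)


class TestPosthoc:
    def test_identical_sessions_give_null_contrast(self, rng):
        df = make_design(rng)
        wide = df.pivot_table(index=["subject", "group"], columns="session", values="value")
        df2 = df.copy()
        df2["value"] = df2.apply(
            lambda r: wide.loc[(r["subject"], r["group"]), "pre"], axis=1
        )
        recs = posthoc_sessions(df2)
        within = [r for r in recs if "pre vs post" in r.contrast]
        assert all(r.statistic == 0 and r.p_raw == 1.0 for r in within)

    def test_family_structure(self, rng):
        recs = posthoc_sessions(make_design(rng))
        assert len(recs) == 9  # 3 within-group + 6 between-group
        assert all(r.family_size == 9 for r in recs)
        assert all(r.p_corrected == min(1.0, r.p_raw * 9) for r in recs)

    def test_planted_shift_detected(self, rng):
        df = make_design(rng, session_shift=(0, 1.5, 0), sd=0.5)
        recs = posthoc_sessions(df)
        lf = next(r for r in recs if r.contrast == "LF: pre vs post")
        assert lf.p_corrected < 0.05


class TestPairedAndCorrelation:
    def test_identical_pairs(self):
        t, df, p = paired_ttest([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0 and p == 1.0 and df == 2

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=(2, 20))
        t, df, p = paired_ttest(x, y)
        ref = sp_stats.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_perfect_line_r_one(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, 3 * x + 1)
        assert r == pytest.approx(1.0)

    def test_p_matches_permutation_estimate(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=15)
        y = 0.5 * x + rng.normal(size=15)
        r, p = pearson_r(x, y)
        perm = sp_stats.permutation_test(
            (x, y),
            lambda a, b: sp_stats.pearsonr(a, b).statistic,
            permutation_type="pairings",
            n_resamples=10_000,
            alternative="two-sided",
            rng=0,
        )
        # Monte-Carlo agreement: 10^4 shuffles give ~0.01 resolution
        assert p == pytest.approx(perm.pvalue, abs=0.02)
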