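"""Statistical battery: correlations, group tests, regressions, ANOVA, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mifmodel.cohort_stats import (
    correlation_screen,
    group_compare,
    interaction_anova,
    is_normal,
    pm_pca,
    ratio_regressions,
    reports_frame,
    two_sample_t_summary,
)

# five fixed rows for the closed-form Pearson check
FIXTURE = pd.DataFrame(
    {"x": [0.30, 0.35, 0.28, 0.41, 0.36], "y": [0.55, 0.70, 0.50, 0.90, 0.72]}
)


class TestCorrelationScreen:
    def test_identity_column(self):
        df = pd.DataFrame({"x": np.random.default_rng(0).normal(size=30)})
        df["y"] = df.x
        (rep,) = correlation_screen(df, ["x"], ["y"])
        assert rep.statistic == pytest.approx(1.0)
        assert rep.p < 1e-10

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=10_000),
                           "y": rng.normal(size=10_000)})
        (rep,) = correlation_screen(df, ["x"], ["y"])
        assert abs(rep.statistic) < 0.05

    def test_matches_hand_computed_pearson(self):
        (rep,) = correlation_screen(FIXTURE, ["x"], ["y"])
        x, y = FIXTURE.x.to_numpy(), FIXTURE.y.to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert rep.statistic == pytest.approx(r_oracle, rel=1e-12)
        assert rep.method == "pearson"

    def test_non_normal_variable_routed_to_spearman(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.lognormal(0, 2, size=80)})
        df["y"] = df.x + rng.normal(0, 0.1, size=80)
        (rep,) = correlation_screen(df, ["x"], ["y"])
        assert rep.method == "spearman" and rep.rank_based

    def test_constant_column_flagged_not_crashed(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        (rep,) = correlation_screen(df, ["x"], ["y"])
        assert rep.method == "constant-column" and np.isnan(rep.statistic)

    def test_bh_adjustment_only_raises_p(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        raw = correlation_screen(df, ["a", "b"], ["c", "d"])
        adj = correlation_screen(df, ["a", "b"], ["c", "d"], adjust=True)
        for r, a in zip(raw, adj):
            assert a.p >= r.p - 1e-12


class TestGroupCompare:
    def test_reproduces_summary_statistic_t(self):
        # published effort-cost baseline contrast: 0.356+/-0.535 (n=15)
        # vs -0.813+/-0.962 (n=12)
        t, p = two_sample_t_summary(0.356, 0.535, 15, -0.813, 0.962, 12)
        assert t == pytest.approx(4.00, abs=0.01)
        assert p < 0.001

    def test_summary_t_agrees_with_raw_data_t(self):
        rng = np.random.default_rng(4)

        def sample(m, sd, n):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return m + sd * z

        a, b = sample(0.356, 0.535, 15), sample(-0.813, 0.962, 12)
        res = stats.ttest_ind(a, b, equal_var=True)
        t_sum, _ = two_sample_t_summary(0.356, 0.535, 15, -0.813, 0.962, 12)
        assert res.statistic == pytest.approx(t_sum, abs=1e-9)

    def test_identical_groups(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(size=12)] * 2)
        groups = np.array(["a"] * 12 + ["b"] * 12)
        rep = group_compare(vals, groups)
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)
        assert rep.p == pytest.approx(1.0)

    def test_rank_branch_matches_exhaustive_rank_oracle(self):
        # heavy-tailed fixture fails the normality gate
        a = np.array([1.0, 2.0, 3.0, 4.0, 100.0, 200.0, 1.5, 2.5])
        b = np.array([5.0, 6.0, 7.0, 300.0, 400.0, 8.0, 9.0])
        vals = np.concatenate([a, b])
        assert not is_normal(vals)
        rep = group_compare(vals, np.array(["g1"] * 8 + ["g2"] * 7))
        ranks = stats.rankdata(vals)
        assert rep.statistic == pytest.approx(ranks[:8].sum())
        assert rep.method == "mann_whitney_u"

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0, 3.0], ["a", "a", "b"])
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], ["a", "a"])


class TestRatioRegressions:
    @staticmethod
    def _table(n=40, seed=0, coupling=1.0):
        rng = np.random.default_rng(seed)
        ratio = rng.normal(0.33, 0.04, n)
        group = np.where(rng.random(n) < 0.5, "isolation", "competition")
        y = coupling * ratio + rng.normal(0, 0.02, n)
        return pd.DataFrame({"gln_glu": ratio, "y": y, "group": group})

    def test_outcome_tracks_ratio(self):
        # outcome = ratio plus a sliver of noise (an exactly collinear
        # outcome gives a zero-residual fit whose group p is undefined)
        df = self._table(coupling=1.0)
        rng = np.random.default_rng(99)
        df["y"] = df.gln_glu + rng.normal(0, 1e-3, len(df))
        reports = ratio_regressions(df, "gln_glu", "y")
        by_term = {r.term: r for r in reports}
        assert by_term["gln_glu"].p < 1e-12
        assert by_term["group"].p > 0.05

    def test_type_i_error_calibrated_under_null(self):
        ps = []
        for seed in range(500):
            df = self._table(n=30, seed=seed, coupling=0.0)
            df["y"] = np.random.default_rng(10_000 + seed).normal(size=30)
            reports = ratio_regressions(df, "gln_glu", "y")
            ps.append(next(r.p for r in reports if r.term == "gln_glu"))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_rank_regression_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(8)
        df = self._table(n=35, seed=8)
        df["y"] = rng.lognormal(0, 2, size=35)  # non-normal outcome
        p1 = {r.term: r.p for r in ratio_regressions(df, "gln_glu", "y")}
        df["y"] = df.y**3  # strictly monotone transform
        p2 = {r.term: r.p for r in ratio_regressions(df, "gln_glu", "y")}
        for term in p1:
            assert p1[term] == pytest.approx(p2[term], rel=1e-9)

    def test_interaction_term_reported_when_requested(self):
        df = self._table(n=40, seed=3)
        reports = ratio_regressions(df, "gln_glu", "y", interaction=True)
        assert any(r.term == "gln_glu:group" for r in reports)

    def test_constant_ratio_flagged(self):
        df = self._table(n=20, seed=1)
        df["gln_glu"] = 0.33
        with pytest.raises(ValueError):
            ratio_regressions(df, "gln_glu", "y")


class TestInteractionAnova:
    @staticmethod
    def _table(n, seed, g_eff=0.0, r_eff=0.0, inter=0.0, noise=1.0):
        rng = np.random.default_rng(seed)
        group = np.where(rng.random(n) < 0.5, "isolation", "competition")
        ratio = rng.normal(0.33, 0.04, n)
        gs = np.where(group == "competition", 1.0, -1.0)
        rs = np.where(ratio >= ratio.mean(), 1.0, -1.0)
        y = g_eff * gs + r_eff * rs + inter * gs * rs + rng.normal(0, noise, n)
        return pd.DataFrame({"y": y, "group": group, "gln_glu": ratio})

    def test_constant_outcome_gives_zero_f(self):
        df = self._table(40, 0)
        df["y"] = 1.0
        reports = interaction_anova(df, "y")
        assert all(r.statistic == 0.0 and r.p == 1.0 for r in reports)

    def test_additive_effects(self):
        df = self._table(400, 1, g_eff=1.0, r_eff=0.8, inter=0.0, noise=0.5)
        by_term = {r.term: r for r in interaction_anova(df, "y")}
        assert by_term["group"].p < 1e-6
        assert by_term["ratio_split"].p < 1e-6
        assert by_term["group:ratio_split"].p > 0.01

    def test_crossover_interaction_dominates(self):
        df = self._table(400, 2, g_eff=0.0, r_eff=0.0, inter=1.0, noise=0.5)
        by_term = {r.term: r for r in interaction_anova(df, "y")}
        assert by_term["group:ratio_split"].statistic > by_term["group"].statistic
        assert by_term["group:ratio_split"].p < 1e-6

    def test_followup_strata_reported(self):
        df = self._table(100, 3, g_eff=1.0)
        terms = [r.term for r in interaction_anova(df, "y")]
        assert "group@low" in terms and "group@high" in terms

    def test_empty_cell_rejected(self):
        df = self._table(30, 4)
        df = df[~((df.group == "competition")
                  & (df.gln_glu >= df.gln_glu.mean()))]
        with pytest.raises(ValueError):
            interaction_anova(df, "y")


class TestPmPca:
    def test_rank_one_structure(self):
        rng = np.random.default_rng(6)
        pattern = rng.uniform(0.2, 0.8, 12)
        pms = [c * pattern for c in rng.uniform(0.5, 1.2, 15)]
        explained, cum = pm_pca(pms)
        assert explained[0] > 0.99
        assert cum[-1] == pytest.approx(1.0)

    def test_isotropic_noise_spreads_evenly(self):
        rng = np.random.default_rng(7)
        pms = [0.5 + rng.normal(0, 0.05, 12) for _ in range(4000)]
        explained, _ = pm_pca(pms)
        assert explained[0] < 0.12  # 1/12 ~ 0.083 plus sampling wiggle

    def test_matches_sklearn_oracle(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(8)
        mats = rng.uniform(0, 1, (10, 12))
        explained, cum = pm_pca(list(mats))
        # 10 subjects give at most 9 nonzero components
        oracle = PCA().fit(mats).explained_variance_ratio_
        assert np.allclose(explained[: len(oracle)], oracle, atol=1e-10)
        assert np.allclose(explained[len(oracle):], 0.0, atol=1e-10)
        assert np.all(np.diff(cum) >= -1e-12)

    def test_minimum_subjects(self):
        with pytest.raises(ValueError):
            pm_pca([np.full(12, 0.5)] * 5)


def test_reports_frame_columns():
    rep = group_compare(
        np.concatenate([np.random.default_rng(0).normal(size=10),
                        np.random.default_rng(1).normal(1, 1, size=10)]),
        np.array(["a"] * 10 + ["b"] * 10),
    )
    df = reports_frame([rep])
    assert list(df.columns) == ["analysis", "term", "statistic", "p", "n",
                                "method"]
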