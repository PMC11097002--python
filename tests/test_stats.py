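import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit as logit_fn

from weedclim.errors import DataError
from weedclim.stats import (anova_tukey_letters, fit_logit_trend, mann_kendall,
                            odds_summary, pca_3var)


def brute_force_s(x):
    return sum(np.sign(b - a) for a, b in itertools.combinations(x, 2))


class TestMannKendall:
    def test_strictly_increasing(self):
        r = mann_kendall([1, 2, 3, 4])
        assert (r.s, r.tau) == (6, 1.0)
        assert r.z > 0

    def test_reversal_antisymmetry(self):
        r = mann_kendall([4, 3, 2, 1])
        assert (r.s, r.tau) == (-6, -1.0)

    def test_tied_series_variance_formula(self):
        # one tie group of size 2: var_S = [4*3*13 - 2*1*9]/18 = 138/18
        r = mann_kendall([1, 3, 2, 3])
        assert r.s == 3
        assert r.var_s == pytest.approx(138 / 18)

    def test_all_equal_degenerates(self):
        r = mann_kendall([5, 5, 5, 5])
        assert (r.tau, r.p, r.z) == (0.0, 1.0, 0.0)

    def test_missing_values_skipped(self):
        assert mann_kendall([1, np.nan, 2, 3, np.nan, 4]).s == 6

    def test_too_short_reports_reason(self):
        r = mann_kendall([1, 2])
        assert not r.valid and "3" in r.reason

    @settings(derandomize=True, max_examples=300)
    @given(st.lists(st.integers(0, 5), min_size=3, max_size=8))
    def test_s_matches_pair_enumeration(self, xs):
        assert mann_kendall(xs).s == brute_force_s(xs)

    def test_tau_matches_scipy_kendall_against_time(self, rng):
        from scipy.stats import kendalltau
        x = rng.normal(size=60) + 0.02 * np.arange(60)
        r = mann_kendall(x)
        assert r.tau == pytest.approx(kendalltau(np.arange(60), x).statistic)


class TestLogisticTrend:
    def test_balanced_response_gives_zero_slope(self):
        t = np.repeat([0.0, 1.0, 2.0], 2)
        y = np.tile([0.0, 1.0], 3)
        assert abs(fit_logit_trend(t, y).slope) < 1e-10

    def test_constant_response_sets_separation_flag(self):
        fit = fit_logit_trend([0, 1, 2, 3], [1, 1, 1, 1])
        assert fit.separation and not fit.converged

    def test_perfectly_ordered_response_flagged_not_fatal(self):
        fit = fit_logit_trend(np.arange(20.0), (np.arange(20) >= 10).astype(float))
        assert fit.separation
        assert np.isfinite(fit.slope)

    def test_slope_invariant_to_time_origin(self, rng):
        t = np.repeat(np.arange(2006.0, 2023.0), 30)
        y = (rng.random(t.size) < expit(-2 + 0.1 * (t - 2014))).astype(float)
        f1 = fit_logit_trend(t, y)
        f2 = fit_logit_trend(t - 2006.0, y)
        assert f1.slope == pytest.approx(f2.slope, abs=1e-6)
        assert f1.se_slope == pytest.approx(f2.se_slope, rel=1e-6)

    def test_matches_statsmodels_mle(self, rng):
        import statsmodels.api as sm
        t = np.repeat(np.arange(17.0), 40)
        y = (rng.random(t.size) < expit(-1 + 0.09 * t)).astype(float)
        fit = fit_logit_trend(t, y)
        ref = sm.Logit(y, sm.add_constant(t)).fit(disp=0)
        assert fit.slope == pytest.approx(ref.params[1], rel=1e-6)
        assert fit.se_slope == pytest.approx(ref.bse[1], rel=1e-4)
        assert fit.intercept == pytest.approx(ref.params[0], rel=1e-6)

    def test_needs_two_distinct_times(self):
        with pytest.raises(DataError):
            fit_logit_trend([1.0, 1.0], [0, 1])


class TestOddsSummary:
    def test_zero_slope_is_no_change(self):
        fit = fit_logit_trend(np.repeat([0.0, 1.0], 4), [0, 1, 0, 1, 0, 1, 0, 1])
        s = odds_summary(fit, 0, 15)
        assert s["odds_ratio_total"] == pytest.approx(1.0)
        assert s["delta_probability"] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_total_odds(self):
        from weedclim.stats import LogitFit
        fit = LogitFit(intercept=-1.0, slope=0.2, se_slope=0.01, z_wald=20,
                       p_wald=0.0, converged=True, separation=False,
                       t_center=7.5, n=100, n_iter=5)
        assert odds_summary(fit, 0, 15)["odds_ratio_total"] == pytest.approx(np.exp(3.0))

    def test_delta_probability_from_inverted_endpoints(self):
        # choose intercept/slope so p(0)=0.10 and p(15)=0.55 exactly
        from weedclim.stats import LogitFit
        b = (logit_fn(0.55) - logit_fn(0.10)) / 15.0
        a = logit_fn(0.10)
        fit = LogitFit(intercept=a, slope=b, se_slope=0.01, z_wald=1, p_wald=0.1,
                       converged=True, separation=False, t_center=0.0, n=10, n_iter=3)
        assert odds_summary(fit, 0, 15)["delta_probability"] == pytest.approx(0.45)


class TestAnovaTukeyLetters:
    def test_identical_groups_share_letters(self, rng):
        x = rng.normal(size=30)
        summaries, f, p, _ = anova_tukey_letters({"a": x, "b": x.copy()})
        letters = {s.name: s.letters for s in summaries}
        assert letters["a"] == letters["b"] != ""

    def test_overwhelming_separation_disjoint_letters(self, rng):
        a = rng.normal(0.0, 1.0, size=30)
        b = rng.normal(10.0, 1.0, size=30)
        summaries, _, p, _ = anova_tukey_letters({"lo": a, "hi": b})
        letters = {s.name: s.letters for s in summaries}
        assert set(letters["lo"]).isdisjoint(letters["hi"])
        assert p < 1e-6

    def test_three_group_a_ab_b_pattern(self):
        """SD sized so only the extreme pair differs -> letters a/ab/b,
        agreeing with direct studentized-range comparisons."""
        from scipy.stats import studentized_range
        # exact means 0/0.5/1 and within-group SD 0.65: the extreme pair's
        # q = 1.0/sqrt(0.65^2/10) = 4.87 > q_crit(3,27) = 3.51, the adjacent
        # pairs' q = 2.43 < q_crit
        n, sd = 10, 0.65
        base = np.linspace(-1, 1, n)
        base = base / base.std(ddof=1) * sd
        groups = {"g0": base + 0.0, "g1": base + 0.5, "g2": base + 1.0}
        summaries, _, _, pairs = anova_tukey_letters(groups)
        letters = {s.name: s.letters for s in summaries}

        # independent oracle: pairwise q statistics vs the alpha=.05 quantile
        means = {g: v.mean() for g, v in groups.items()}
        mse = np.mean([v.var(ddof=1) for v in groups.values()])
        qcrit = studentized_range.ppf(0.95, 3, 3 * n - 3)
        sig = {frozenset((a, b)): abs(means[a] - means[b]) / np.sqrt(mse / n) > qcrit
               for a, b in itertools.combinations(groups, 2)}
        assert sig[frozenset(("g0", "g2"))]
        assert not sig[frozenset(("g0", "g1"))] and not sig[frozenset(("g1", "g2"))]

        assert set(letters["g0"]).isdisjoint(letters["g2"])
        assert set(letters["g1"]) & set(letters["g0"])
        assert set(letters["g1"]) & set(letters["g2"])

    def test_studentized_range_quantile_matches_published_table(self):
        from scipy.stats import studentized_range
        # q(alpha=.05, k=3, df=27) from published tables
        assert studentized_range.ppf(0.95, 3, 27) == pytest.approx(3.5064, abs=1e-3)

    def test_zero_variance_equal_means_single_letter(self):
        summaries, f, p, _ = anova_tukey_letters({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert f == 0.0
        assert summaries[0].letters == summaries[1].letters

    def test_matches_statsmodels_tukey_significance(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        groups = {f"g{i}": rng.normal(i * 0.4, 1.0, 25) for i in range(4)}
        _, _, _, pairs = anova_tukey_letters(groups)
        data = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        ref = pairwise_tukeyhsd(data, labels, alpha=0.05)
        ref_pairs = list(itertools.combinations(ref.groupsunique, 2))
        ref_sig = {frozenset(p): bool(s) for p, s in zip(ref_pairs, ref.reject)}
        for row in pairs:
            assert row["significant"] == ref_sig[frozenset((row["group_a"], row["group_b"]))]


class TestPCA:
    def test_loadings_orthonormal_and_explained_sums_to_one(self, rng):
        X = rng.normal(size=(200, 3))
        res = pca_3var(X)
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(3), atol=1e-10)
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(res.explained) <= 1e-12)

    def test_perfectly_correlated_pair_shares_pc1_weight(self, rng):
        a = rng.normal(size=500)
        X = np.column_stack([a, a * 2.0 + 1.0, rng.normal(size=500)])
        res = pca_3var(X)
        assert abs(res.loadings[0, 0]) == pytest.approx(abs(res.loadings[1, 0]), abs=1e-10)

    def test_isotropic_data_equal_fractions(self, rng):
        X = rng.normal(size=(20000, 3))
        res = pca_3var(X)
        np.testing.assert_allclose(res.explained, 1 / 3, atol=0.02)

    def test_reconstruction_of_standardized_data(self, rng):
        X = rng.normal(size=(50, 3)) @ rng.normal(size=(3, 3))
        res = pca_3var(X)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        np.testing.assert_allclose(res.scores @ res.loadings.T, Xs, atol=1e-8)

    def test_planted_correlation_sign_structure(self, rng):
        """elevation-rzsm correlated at r=0.7, lst independent: the
        correlated pair loads PC1 with the same sign, lst dominates
        another component — matching the population eigenstructure."""
        n = 2000
        elev = rng.normal(size=n)
        rzsm = 0.7 * elev + np.sqrt(1 - 0.49) * rng.normal(size=n)
        lst = rng.normal(size=n)
        res = pca_3var(np.column_stack([elev, lst, rzsm]),
                       variables=["elev", "lst", "rzsm"])
        l1 = res.loadings[:, 0]
        assert np.sign(l1[0]) == np.sign(l1[2])
        assert abs(l1[0]) > 0.5 and abs(l1[2]) > 0.5 and abs(l1[1]) < 0.3
        assert np.argmax(np.abs(res.loadings[1, :])) != 0
        # population eigenvalues of [[1,0,.7],[0,1,0],[.7,0,1]] are 1.7, 1, .3
        np.testing.assert_allclose(res.eigenvalues, [1.7, 1.0, 0.3], atol=0.12)

    def test_zero_variance_variable_named(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0) ** 2])
        with pytest.raises(DataError, match="elev"):
            pca_3var(X, variables=["elev", "lst", "rzsm"])
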