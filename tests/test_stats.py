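import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from topobrain.stats import (
    SeparationError,
    bh_adjust,
    bootstrap_or_ci,
    cohens_d,
    logistic_fit,
    posthoc_power,
    roc_auc,
    wilcoxon_rank_sum,
)


def table_from_2x2(a, b, c, d):
    """Cohort with binary covariate: a=exposed cases, b=exposed controls,
    c=unexposed cases, d=unexposed controls."""
    rows = (
        [{"group": 1, "x": 1}] * a
        + [{"group": 0, "x": 1}] * b
        + [{"group": 1, "x": 0}] * c
        + [{"group": 0, "x": 0}] * d
    )
    return pd.DataFrame(rows)


class TestWilcoxon:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        _, p = wilcoxon_rank_sum(x, x)
        assert p >= 0.99

    def test_exact_extreme(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=15)
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_normal_approx_close_to_exact_n5(self):
        # all attainable rank-sum values for tie-free n1 = n2 = 5
        n1 = n2 = 5
        n = n1 + n2
        sums = np.fromiter(
            (sum(c) for c in itertools.combinations(range(1, n + 1), n1)),
            dtype=float,
        )
        mean = n1 * (n + 1) / 2
        var = n1 * n2 * (n + 1) / 12
        for w in np.unique(sums):
            exact = min(1.0, 2 * min((sums <= w).mean(), (sums >= w).mean()))
            z = max(0.0, (abs(w - mean) - 0.5) / math.sqrt(var))
            approx = min(1.0, 2 * sps.norm.sf(z))
            assert abs(exact - approx) <= 0.02

    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 6, 30).astype(float)
        y = rng.integers(1, 7, 25).astype(float)
        _, p = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", use_continuity=True,
            method="asymptotic",
        ).pvalue
        assert p == pytest.approx(ref, abs=1e-10)


class TestEffectSizeAndPower:
    def test_mean_equal_gives_zero(self):
        assert cohens_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_unit_effect_hand_case(self):
        h = math.sqrt(2) / 2
        x = [1 - h, 1 + h]  # mean 1, sd 1
        y = [-h, h]  # mean 0, sd 1
        assert cohens_d(x, y) == pytest.approx(1.0)

    def test_antisymmetric(self, rng):
        x, y = rng.normal(size=10), rng.normal(1.0, 1.0, size=12)
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])

    def test_power_null_equals_alpha(self):
        assert posthoc_power(0.0, 20, 20, 0.05) == pytest.approx(0.05)

    def test_power_saturates(self):
        assert posthoc_power(5.0, 30, 30, 0.05) == pytest.approx(1.0, abs=1e-6)

    def test_power_against_independent_oracle(self):
        # statsmodels solves the same noncentral-t problem independently
        from statsmodels.stats.power import TTestIndPower

        for d, n in [(0.55, 30), (0.57, 30), (0.3, 50)]:
            ref = TTestIndPower().power(d, nobs1=n, alpha=0.05, ratio=1.0)
            assert posthoc_power(d, n, n, 0.05) == pytest.approx(ref, abs=1e-6)

    def test_moderate_effect_power_near_half(self):
        # the cohort-sized regime: d ~ 0.55 at n = 30 + 30 is underpowered
        assert posthoc_power(0.55, 30, 30, 0.05) == pytest.approx(0.55, abs=0.01)


class TestLogisticFit:
    def test_two_by_two_closed_form(self):
        fit = logistic_fit(table_from_2x2(9, 3, 21, 27), "group", ["x"])
        assert fit.odds_ratios[0] == pytest.approx(9 * 27 / (3 * 21), abs=1e-4)

    def test_independent_covariate_or_one(self):
        fit = logistic_fit(table_from_2x2(10, 10, 15, 15), "group", ["x"])
        assert fit.odds_ratios[0] == pytest.approx(1.0, abs=1e-6)

    def test_random_2x2_matches_log_cross_ratio(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(1, 30, size=4)
            fit = logistic_fit(table_from_2x2(a, b, c, d), "group", ["x"])
            assert fit.coefficients[0] == pytest.approx(
                math.log(a * d / (b * c)), abs=1e-6
            )

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 80
        X = rng.normal(size=(n, 3))
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * X[:, 0] - X[:, 1])))).astype(float)
        tab = pd.DataFrame(X, columns=["a", "b", "c"])
        tab["group"] = y
        fit = logistic_fit(tab, "group", ["a", "b", "c"])
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params[1:], atol=1e-5)
        np.testing.assert_allclose(fit.std_errors, ref.bse[1:], atol=1e-5)

    def test_parameter_recovery_simulation(self):
        # data simulated from the model class: mean estimated log-OR
        # within 3 Monte-Carlo SEs of the truth
        rng = np.random.default_rng(3)
        beta = np.array([0.7, -0.5, 0.0, 0.3])
        est = []
        for _ in range(500):
            X = rng.normal(size=(60, 4))
            p = 1 / (1 + np.exp(-(X @ beta)))
            y = (rng.random(60) < p).astype(float)
            if y.min() == y.max():
                continue
            tab = pd.DataFrame(X, columns=list("abcd"))
            tab["group"] = y
            try:
                est.append(logistic_fit(tab, "group", list("abcd")).coefficients)
            except SeparationError:
                continue
        est = np.array(est)
        mc_se = est.std(axis=0, ddof=1) / math.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0) - beta) <= 3 * mc_se + 0.05)

    def test_perfect_separation_raises_named_error(self):
        tab = pd.DataFrame(
            {"group": [0, 0, 0, 1, 1, 1], "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}
        )
        with pytest.raises(SeparationError, match="x"):
            logistic_fit(tab, "group", ["x"])

    def test_rank_deficient_design_errors(self):
        tab = table_from_2x2(5, 5, 5, 5)
        tab["x2"] = 2 * tab["x"]
        with pytest.raises(ValueError, match="rank"):
            logistic_fit(tab, "group", ["x", "x2"])

    def test_single_class_outcome_errors(self):
        tab = pd.DataFrame({"group": [1, 1, 1], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            logistic_fit(tab, "group", ["x"])

    def test_auc_reported_from_fitted_probs(self, rng):
        tab = table_from_2x2(20, 5, 10, 25)
        fit = logistic_fit(tab, "group", ["x"])
        assert fit.auc == pytest.approx(
            roc_auc(fit.fitted_probs, tab["group"].to_numpy())
        )


class TestBHAdjust:
    def test_perimeter_model_pvalues_collapse(self):
        adj = bh_adjust([0.025, 0.029, 0.014, 0.035])
        np.testing.assert_allclose(np.round(adj, 3), [0.035] * 4)

    def test_area_model_pvalues(self):
        adj = bh_adjust([0.026, 0.024, 0.021, 0.036])
        np.testing.assert_allclose(
            np.round(adj, 3), [0.035, 0.035, 0.035, 0.036]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_adjusted_at_least_raw_and_order_preserved(self, rng):
        p = rng.uniform(size=20)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=11)
        perm = rng.permutation(11)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=15)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestBootstrap:
    @staticmethod
    def _simulate(rng, n=60, beta=math.log(2.0)):
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.2 + beta * x)))
        y = (rng.random(n) < p).astype(float)
        return pd.DataFrame({"group": y, "x": x})

    def test_deterministic_given_seed(self, rng):
        tab = self._simulate(np.random.default_rng(1))
        a = bootstrap_or_ci(tab, "group", ["x"], B=200, seed=42)
        b = bootstrap_or_ci(tab, "group", ["x"], B=200, seed=42)
        assert a == b

    def test_nominal_coverage(self):
        # 95% percentile CI should contain the true OR = 2 in >= 90% of
        # outer replications
        outer = np.random.default_rng(12345)
        hits = 0
        for k in range(50):
            tab = self._simulate(np.random.default_rng(outer.integers(2**31)))
            try:
                ci = bootstrap_or_ci(tab, "group", ["x"], B=2000, seed=k)
            except (SeparationError, ValueError):
                continue
            lo, hi = ci["x"]
            hits += lo <= 2.0 <= hi
        assert hits >= 45

    def test_redraw_exhaustion_errors(self):
        # nearly separated 4-subject table: most resamples are single-class
        # or completely separated, exceeding the 50% failure budget
        tab = pd.DataFrame(
            {"group": [0, 0, 1, 1], "x": [1.0, 10.0, 9.0, 11.0]}
        )
        with pytest.raises(RuntimeError, match="exhaustion"):
            bootstrap_or_ci(tab, "group", ["x"], B=100, seed=0)

    def test_small_B_rejected(self):
        tab = self._simulate(np.random.default_rng(2))
        with pytest.raises(ValueError):
            bootstrap_or_ci(tab, "group", ["x"], B=50, seed=0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_enumerated_pairs(self):
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_complement_identity(self, rng):
        s = rng.normal(size=30)
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        assert roc_auc(s, y) + roc_auc(-s, y) == pytest.approx(1.0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestCohortSpreadsheet:
    def test_column_mapping_roundtrip(self, tmp_path, rng):
        from topobrain.stats import load_cohort_xlsx

        df = pd.DataFrame(
            {
                "NPSLE": [0, 1, 0, 1],
                "Age (years)": [40.0, 35.0, 50.0, 44.0],
                "Perimeter1": rng.normal(7, 1, 4),
            }
        )
        p = tmp_path / "cohort.xlsx"
        df.to_excel(p, index=False)
        out = load_cohort_xlsx(
            p,
            {"NPSLE": "group", "Age (years)": "age",
             "Perimeter1": "dim1_perimeter"},
        )
        assert list(out.columns) == ["group", "age", "dim1_perimeter"]
        np.testing.assert_allclose(out["dim1_perimeter"], df["Perimeter1"])


class TestPropertyBased:
    from hypothesis import given, settings
    from hypothesis import strategies as hst

    @given(
        hst.lists(
            hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30
        )
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_bh_dominates_raw_and_respects_bounds(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    @given(
        hst.lists(hst.floats(-50, 50), min_size=4, max_size=40),
        hst.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_auc_complement_identity(self, scores, label_seed):
        y = np.random.default_rng(label_seed).integers(0, 2, len(scores))
        y[:2] = [0, 1]  # both classes present
        s = np.asarray(scores)
        assert roc_auc(s, y) + roc_auc(-s, y) == pytest.approx(1.0)
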