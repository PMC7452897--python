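import numpy as np
import pandas as pd
import pytest
from scipy import stats

import radsurv as rs

from .oracles import brute_auc_at_horizon, brute_cindex, brute_logrank


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = rs.km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert km.at(2.5) == pytest.approx(0.5)
        assert km.at(0.5) == 1.0
        assert km.at(4.0) == 0.0

    def test_product_limit_with_censoring_by_hand(self):
        # events at 1 and 3, censored at 2: S(1) = 2/3, S(3) = 0
        km = rs.km_estimate([1, 2, 3], [1, 0, 1])
        assert km.at(1) == pytest.approx(2 / 3)
        assert km.at(3) == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        km = rs.km_estimate([5, 8, 2], [0, 0, 0])
        assert np.all(km.survival == 1.0)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            rs.km_estimate([-1, 2], [1, 1])

    def test_monotone_within_unit_interval(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 100)
        e = rng.integers(0, 2, 100)
        km = rs.km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.survival >= 0) & (km.survival <= 1))


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0]
        stat, p = rs.logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_worked_example_matches_brute_force(self):
        t1, e1 = [2, 4, 6], [1, 1, 0]
        t2, e2 = [1, 3, 5], [1, 0, 1]
        stat, p = rs.logrank_test(t1, e1, t2, e2)
        expected = brute_logrank(t1, e1, t2, e2)
        assert stat == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-9)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        t1, t2 = rng.exponential(10, 30), rng.exponential(15, 40)
        e1, e2 = rng.integers(0, 2, 30), rng.integers(0, 2, 40)
        s_ab, p_ab = rs.logrank_test(t1, e1, t2, e2)
        s_ba, p_ba = rs.logrank_test(t2, e2, t1, e1)
        assert s_ab == pytest.approx(s_ba) and p_ab == pytest.approx(p_ba)

    def test_no_events_warns_p_one(self):
        with pytest.warns(UserWarning, match="no events"):
            _, p = rs.logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert p == 1.0

    def test_type_one_error_calibrated(self):
        # null simulation: equal exponential arms
        rng = np.random.default_rng(2)
        rejections = 0
        n_reps = 500
        for _ in range(n_reps):
            t = rng.exponential(20, 200)
            c = rng.exponential(40, 200)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            _, p = rs.logrank_test(time[:100], event[:100], time[100:], event[100:])
            rejections += p < 0.05
        assert 0.03 <= rejections / n_reps <= 0.07


class TestCoxFit:
    def test_hand_solved_two_group_partial_likelihood(self):
        # 4 subjects, no ties: solve the score equation independently
        df = pd.DataFrame(
            {"time_months": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1],
             "x": [1.0, 0.0, 1.0, 0.0]}
        )
        def score_fn(b):
            # events in time order; risk sets {all}, {2,3,4}, {3,4}, {4}
            eb = np.exp(b)
            return (
                (1 - 2 * eb / (2 * eb + 2))
                + (0 - eb / (eb + 2))
                + (1 - eb / (eb + 1))
                + (0 - 0)
            )
        from scipy.optimize import brentq

        b_hand = brentq(score_fn, -5, 5)
        fit = rs.fit_cox(df, covariates=["x"])
        assert fit.coefficients["x"] == pytest.approx(b_hand, abs=1e-4)
        assert fit.hazard_ratios["x"] == pytest.approx(np.exp(b_hand), abs=1e-4)

    def test_hr_ci_consistent_with_beta_covariance(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 500).astype(float)
        t = rng.exponential(1 / (0.02 * np.exp(0.7 * x)))
        df = pd.DataFrame({"time_months": t, "event": 1, "x": x})
        fit = rs.fit_cox(df, covariates=["x"])
        se = np.sqrt(fit.covariance.loc["x", "x"])
        assert fit.ci_lower["x"] == pytest.approx(
            np.exp(fit.coefficients["x"] - 1.96 * se), rel=1e-3
        )

    def test_coverage_of_true_hazard_ratio(self):
        rng = np.random.default_rng(4)
        covered = 0
        n_reps = 60
        for _ in range(n_reps):
            x = rng.integers(0, 2, 600).astype(float)
            t = rng.exponential(1 / (0.02 * np.exp(np.log(2) * x)))
            c = np.minimum(rng.exponential(80, 600), 60)
            df = pd.DataFrame(
                {"time_months": np.minimum(t, c), "event": (t <= c).astype(int), "x": x}
            )
            fit = rs.fit_cox(df, covariates=["x"])
            covered += fit.ci_lower["x"] <= 2.0 <= fit.ci_upper["x"]
        assert covered / n_reps >= 0.90

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time_months": [1, 2, 3], "event": [1, 1, 0], "x": 1.0})
        with pytest.raises(ValueError, match="constant"):
            rs.fit_cox(df, covariates=["x"])


class TestTimeDependentAUC:
    def test_perfect_ranking(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(30, 200)
        auc = rs.time_dependent_auc(-t, t, np.ones(200), horizons=(12.0,))
        assert auc[12.0] == pytest.approx(1.0)

    def test_null_marker_near_half(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(30, 500)
        marker = rng.standard_normal(500)
        auc = rs.time_dependent_auc(marker, t, np.ones(500), horizons=(12.0, 24.0))
        for v in auc.values():
            assert v == pytest.approx(0.5, abs=0.05)

    def test_no_censoring_matches_pair_counting(self):
        rng = np.random.default_rng(7)
        n = 120
        marker = rng.standard_normal(n)
        t = rng.exponential(30 * np.exp(-0.5 * marker))
        e = np.ones(n)
        auc = rs.time_dependent_auc(marker, t, e, horizons=(12.0,))
        assert auc[12.0] == pytest.approx(
            brute_auc_at_horizon(marker, t, e, 12.0), abs=1e-9
        )

    def test_horizon_beyond_follow_up_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            rs.time_dependent_auc([1, 2], [5, 6], [1, 1], horizons=(10.0,))


class TestHarrellC:
    def test_perfectly_concordant(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        c, (lo, hi) = rs.harrell_cindex(-t, t, np.ones(4))
        assert c == 1.0

    def test_three_patient_enumeration(self):
        marker = np.array([3.0, 1.0, 2.0])
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 0, 1])
        c, _ = rs.harrell_cindex(marker, t, e)
        assert c == pytest.approx(brute_cindex(marker, t, e))

    def test_random_marker_near_half_and_matches_sksurv(self):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(8)
        n = 500
        marker = rng.standard_normal(n)
        t = rng.exponential(30, n)
        e = rng.integers(0, 2, n).astype(bool)
        c, (lo, hi) = rs.harrell_cindex(marker, t, e)
        assert c == pytest.approx(0.5, abs=0.05)
        ref = concordance_index_censored(e, t, marker)[0]
        assert c == pytest.approx(ref, abs=1e-9)
        assert lo < c < hi

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        marker = rng.standard_normal(100)
        t = rng.exponential(20, 100)
        e = rng.integers(0, 2, 100)
        c1, _ = rs.harrell_cindex(marker, t, e)
        c2, _ = rs.harrell_cindex(np.exp(2 * marker), t, e)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            rs.harrell_cindex([1.0, 2.0], [5.0, 5.0], [1, 1])


class TestBaselineComparison:
    def test_identical_tables_null(self):
        rng = np.random.default_rng(10)
        a = pd.DataFrame(
            {"age": rng.normal(55, 10, 60), "cea": rng.choice(["<5", ">=5"], 60)}
        )
        res = rs.compare_baselines(
            a, a.copy(), {"age": "continuous", "cea": "categorical"}
        )
        assert (res["p"] > 0.99).all()

    def test_small_counts_route_to_fisher(self):
        a = pd.DataFrame({"x": ["y"] * 3 + ["n"] * 2})
        b = pd.DataFrame({"x": ["y"] * 1 + ["n"] * 4})
        res = rs.compare_baselines(a, b, {"x": "categorical"})
        assert res.loc["x", "test"] == "fisher"

    def test_chi_square_closed_form(self):
        a = pd.DataFrame({"x": ["y"] * 30 + ["n"] * 70})
        b = pd.DataFrame({"x": ["y"] * 50 + ["n"] * 50})
        res = rs.compare_baselines(a, b, {"x": "categorical"})
        # direct 2x2 chi-square without continuity correction
        obs = np.array([[30, 70], [50, 50]])
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        expected = np.outer(row, col) / n
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert res.loc["x", "test"] == "chi2"
        assert res.loc["x", "p"] == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-9)

    def test_nonnormal_routes_to_mann_whitney(self):
        rng = np.random.default_rng(11)
        a = pd.DataFrame({"v": rng.exponential(1, 80)})
        b = pd.DataFrame({"v": rng.exponential(1.5, 80)})
        res = rs.compare_baselines(a, b, {"v": "continuous"})
        assert res.loc["v", "test"] == "mann-whitney"
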