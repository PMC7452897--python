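import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import radsurv as rs
from radsurv.signature import _cox_univariate_many

from .conftest import make_survival_features


class TestNormalizeFeatures:
    def test_primary_fit(self):
        feats, _, _ = make_survival_features(0, n=50)
        normed, stats = rs.normalize_features(feats)
        assert np.allclose(normed.mean(), 0, atol=1e-12)
        assert np.allclose(normed.std(ddof=0), 1, atol=1e-12)

    def test_validation_reuses_primary_stats(self):
        feats, _, _ = make_survival_features(0, n=50)
        _, stats = rs.normalize_features(feats)
        shifted = feats + 5.0
        with_stats, _ = rs.normalize_features(shifted, stats)
        refit, _ = rs.normalize_features(shifted)
        # applying stored stats must preserve the shift; refitting hides it
        assert with_stats.mean().mean() == pytest.approx(
            (5.0 / stats["sd"]).mean(), rel=1e-9
        )
        assert abs(refit.mean().mean()) < 1e-12

    def test_constant_feature_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            rs.normalize_features(df)

    def test_missing_feature_in_stats_rejected(self):
        feats, _, _ = make_survival_features(0, n=20)
        _, stats = rs.normalize_features(feats[["true0"]])
        with pytest.raises(KeyError, match="absent"):
            rs.normalize_features(feats, stats)


class TestUnivariateScreen:
    def test_strong_feature_significant(self):
        feats, surv, _ = make_survival_features(1, n=300, betas=(1.0,))
        screen = rs.univariate_cox_screen(feats, surv)
        assert screen.loc["true0", "p"] < 1e-3

    def test_null_features_uniform_pvalues(self):
        # 1000 independent null features in one vectorized screen
        feats, surv, _ = make_survival_features(2, n=150, n_noise=1000, betas=())
        screen = rs.univariate_cox_screen(feats, surv)
        frac = (screen["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_matches_lifelines_fit(self):
        from lifelines import CoxPHFitter

        feats, surv, _ = make_survival_features(3, n=120, n_noise=2, betas=(0.7,))
        X = feats.to_numpy()
        beta, se, conv = _cox_univariate_many(
            X, surv["time_months"].to_numpy(), surv["event"].to_numpy()
        )
        for j, col in enumerate(feats.columns):
            df = pd.DataFrame(
                {"t": surv["time_months"], "e": surv["event"], "x": X[:, j]}
            )
            cph = CoxPHFitter().fit(df, "t", "e")
            assert beta[j] == pytest.approx(cph.params_["x"], abs=1e-5)
            assert se[j] == pytest.approx(cph.standard_errors_["x"], abs=1e-5)

    def test_zero_variance_feature_warns_p1(self):
        feats, surv, _ = make_survival_features(4, n=60)
        feats["flat"] = 1.0
        with pytest.warns(UserWarning, match="degenerate"):
            screen = rs.univariate_cox_screen(feats, surv)
        assert screen.loc["flat", "p"] == 1.0


class TestCoarseFilter:
    def test_enumerated_rule(self):
        p = pd.Series(
            np.arange(0.01, 0.11, 0.01), index=[f"f{i}" for i in range(10)]
        )
        kept = rs.coarse_filter(p, fraction=0.2, alpha=0.1)
        assert kept == ["f0", "f1"]  # p = 0.01, 0.02

    def test_no_significant_features_empty(self):
        p = pd.Series([0.1, 0.5, 0.9], index=list("abc"))
        assert rs.coarse_filter(p) == []

    def test_cap_at_20pct_of_1240(self):
        rng = np.random.default_rng(0)
        p = pd.Series(rng.uniform(0, 0.09, 1240), index=[f"f{i}" for i in range(1240)])
        kept = rs.coarse_filter(p)
        assert len(kept) == 248  # ceil(0.2 * 1240)

    def test_within_significant_mode(self):
        p = pd.Series(
            np.arange(0.01, 0.11, 0.01), index=[f"f{i}" for i in range(10)]
        )
        kept = rs.coarse_filter(p, fraction=0.2, alpha=0.1, mode="within_significant")
        assert kept == ["f0", "f1"]  # 9 significant -> ceil(1.8) = 2


def brute_force_prune(table: pd.DataFrame, cutoff: float) -> list[str]:
    """Step-by-step independent replay of the documented greedy rule."""
    retained = list(table.columns)
    order = {c: i for i, c in enumerate(table.columns)}
    while len(retained) > 1:
        best_pair, best_r = None, cutoff
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                r = abs(np.corrcoef(table[a], table[b])[0, 1])
                if np.isnan(r):
                    r = 0.0
                if r > best_r or (best_pair and r == best_r):
                    if best_pair is None or r > best_r or tuple(sorted((a, b))) < best_pair:
                        best_pair, best_r = tuple(sorted((a, b))), r
        if best_pair is None:
            break
        a, b = best_pair
        def mean_abs(f):
            vals = [
                abs(np.nan_to_num(np.corrcoef(table[f], table[g])[0, 1]))
                for g in retained
                if g != f
            ]
            return np.mean(vals)
        ma, mb = mean_abs(a), mean_abs(b)
        if ma > mb:
            drop = a
        elif mb > ma:
            drop = b
        else:
            drop = a if order[a] > order[b] else b
        retained.remove(drop)
    return retained


class TestCorrelationPrune:
    def test_duplicate_column_collapses(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        table = pd.DataFrame({"a": x, "b": x})
        assert len(rs.correlation_prune(table)) == 1

    def test_known_structure_matches_oracle(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(60)
        table = pd.DataFrame(
            {
                "a": z + rng.normal(0, 0.1, 60),
                "b": z + rng.normal(0, 0.1, 60),
                "c": rng.standard_normal(60),
                "d": z + rng.normal(0, 0.8, 60),
            }
        )
        assert rs.correlation_prune(table, 0.6) == brute_force_prune(table, 0.6)

    @pytest.mark.parametrize("seed", range(20))
    def test_output_never_violates_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.standard_normal((40, 3))
        mix = rng.standard_normal((3, 8))
        table = pd.DataFrame(
            base @ mix + 0.5 * rng.standard_normal((40, 8)),
            columns=[f"f{i}" for i in range(8)],
        )
        kept = rs.correlation_prune(table, 0.6)
        if len(kept) > 1:
            sub = table[kept].corr().abs().to_numpy()
            np.fill_diagonal(sub, 0)
            assert sub.max() <= 0.6 + 1e-12
        assert kept == brute_force_prune(table, 0.6)


class TestLassoCox:
    def test_full_shrinkage_errors(self):
        feats, surv, _ = make_survival_features(5, n=100, betas=(0.8,))
        normed, stats = rs.normalize_features(feats)
        with pytest.raises(ValueError, match="zero"):
            rs.fit_lasso_cox(
                normed, surv, stats, n_folds=3, seed=0, alphas=[1e6], lambda_rule="min"
            )

    def test_planted_feature_recovery(self):
        hits, spear = 0, []
        n_reps = 10
        for seed in range(n_reps):
            feats, surv, true_lp = make_survival_features(
                100 + seed, n=400, n_noise=100, betas=(1.0, -1.0, 1.0)
            )
            normed, stats = rs.normalize_features(feats)
            model = rs.fit_lasso_cox(normed, surv, stats, n_folds=10, seed=seed)
            sel = set(model.selected_features)
            truths = {"true0", "true1", "true2"}
            if truths <= sel and len(sel - truths) <= 10:
                hits += 1
            spear.append(spearmanr(rs.score(model, feats), true_lp).statistic)
        assert hits >= 0.9 * n_reps
        assert np.mean(spear) >= 0.7


class TestScoreAndStratify:
    def _toy_model(self):
        stats = pd.DataFrame({"mean": [1.0, 2.0], "sd": [2.0, 0.5]}, index=["a", "b"])
        return rs.SignatureModel(
            selected_features=["a", "b"],
            coefficients=np.array([0.5, -1.0]),
            normalization_stats=stats,
            lambda_=0.1,
            seed=0,
        )

    def test_hand_computed_scores(self):
        model = self._toy_model()
        feats = pd.DataFrame({"a": [3.0], "b": [1.0]}, index=["p1"])
        # z_a = (3-1)/2 = 1 ; z_b = (1-2)/0.5 = -2 ; score = 0.5*1 + (-1)*(-2)
        assert rs.score(model, feats)["p1"] == pytest.approx(2.5)

    def test_zero_normalized_features_score_zero(self):
        model = self._toy_model()
        feats = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["p1"])
        assert rs.score(model, feats)["p1"] == 0.0

    def test_missing_feature_rejected(self):
        model = self._toy_model()
        with pytest.raises(KeyError, match="missing"):
            rs.score(model, pd.DataFrame({"a": [1.0]}))

    def test_median_cutoff_enumeration(self):
        model = self._toy_model()
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("vwxyz"))
        rs.fit_cutoff(model, scores)
        assert model.cutoff == 3.0
        groups = rs.stratify(model, scores)
        assert list(groups) == ["low", "low", "low", "high", "high"]

    def test_validation_shift_moves_to_high_without_moving_cutoff(self):
        model = self._toy_model()
        rs.fit_cutoff(model, pd.Series([1.0, 2.0, 3.0]))
        shifted = pd.Series([10.0, 11.0])
        assert (rs.stratify(model, shifted) == "high").all()
        assert model.cutoff == 2.0

    def test_cutoff_required(self):
        model = self._toy_model()
        with pytest.raises(ValueError, match="cutoff"):
            rs.stratify(model, pd.Series([1.0]))

    def test_json_round_trip(self, tmp_path):
        model = self._toy_model()
        model.cutoff = 0.25
        model.to_json(tmp_path / "m.json")
        back = rs.SignatureModel.from_json(tmp_path / "m.json")
        assert back.selected_features == model.selected_features
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        assert back.cutoff == model.cutoff
        feats = pd.DataFrame({"a": [3.0], "b": [1.0]})
        assert rs.score(back, feats)[0] == rs.score(model, feats)[0]


class TestEndToEndSelection:
    def test_stage_nesting_and_score_quality(self):
        feats, surv, true_lp = make_survival_features(
            7, n=300, n_noise=60, betas=(1.0, -0.8)
        )
        model, screening = rs.build_signature(feats, surv, n_folds=5, seed=7)
        assert set(screening.selected) <= set(screening.pruned_set)
        assert set(screening.pruned_set) <= set(screening.coarse_set)
        assert len(screening.coarse_set) <= int(np.ceil(0.2 * feats.shape[1]))
        assert model.cutoff is not None
        sc = rs.score(model, feats)
        assert spearmanr(sc, true_lp).statistic > 0.5
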