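import numpy as np
import pandas as pd
import pytest

import radsurv as rs

from .oracles import brute_net_benefit


def _sim_cox_data(seed, n=300, beta1=0.8, beta2=-0.5, censor=True):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {"x1": rng.standard_normal(n), "x2": rng.integers(0, 2, n).astype(float)}
    )
    lp = beta1 * df.x1 + beta2 * df.x2
    t = rng.exponential(1 / (0.02 * np.exp(lp)))
    if censor:
        c = np.minimum(rng.exponential(100, n), 60)
    else:
        c = np.full(n, np.inf)
    df["time_months"] = np.minimum(t, c)
    df["event"] = (t <= c).astype(int)
    return df


class TestNomogram:
    def test_single_binary_covariate_point_scale(self):
        df = _sim_cox_data(0)[["x2", "time_months", "event"]]
        nom = rs.build_nomogram(df, ["x2"])
        pts0 = nom.total_points(pd.Series({"x2": 0.0}))
        pts1 = nom.total_points(pd.Series({"x2": 1.0}))
        assert sorted([pts0, pts1]) == [0.0, 100.0]

    def test_predictions_match_cox_model_exactly(self):
        df = _sim_cox_data(1)
        nom = rs.build_nomogram(df, ["x1", "x2"])
        cph = nom.cox._fitter
        sf = cph.predict_survival_function(df.iloc[[7]][["x1", "x2"]])
        for h in (12.0, 24.0, 36.0):
            idx = sf.index.searchsorted(h, side="right") - 1
            direct = float(sf.iloc[idx, 0])
            assert rs.predict_dmfs(nom, df.iloc[7], h) == pytest.approx(
                direct, abs=1e-9
            )

    def test_zero_covariates_give_baseline(self):
        df = _sim_cox_data(2)
        nom = rs.build_nomogram(df, ["x1", "x2"])
        row = pd.Series({"x1": 0.0, "x2": 0.0})
        for h in (12.0, 36.0):
            assert rs.predict_dmfs(nom, row, h) == pytest.approx(
                nom.baseline_survival[h], abs=1e-12
            )

    def test_monotone_in_horizon(self):
        df = _sim_cox_data(3)
        nom = rs.build_nomogram(df, ["x1", "x2"])
        probs = [rs.predict_dmfs(nom, df.iloc[4], h) for h in (12.0, 24.0, 36.0)]
        assert probs[0] >= probs[1] >= probs[2]

    def test_unfitted_horizon_rejected(self):
        df = _sim_cox_data(4)
        nom = rs.build_nomogram(df, ["x1"])
        with pytest.raises(ValueError, match="horizon"):
            rs.predict_dmfs(nom, df.iloc[0], 18.0)

    def test_signature_nomogram_dominates_clinical(self):
        # informative marker + weak clinical covariate: the richer model's
        # C-index should win in nearly every replicate
        wins = 0
        n_reps = 10
        for seed in range(n_reps):
            rng = np.random.default_rng(200 + seed)
            n = 500
            risk = rng.standard_normal(n)
            clin = rng.integers(0, 2, n).astype(float)
            lp = 1.0 * risk + 0.2 * clin
            t = rng.exponential(1 / (0.02 * np.exp(lp)))
            c = np.minimum(rng.exponential(100, n), 60)
            df = pd.DataFrame(
                {
                    "time_months": np.minimum(t, c),
                    "event": (t <= c).astype(int),
                    "clin": clin,
                    "signature": risk,
                }
            )
            nom_c = rs.build_nomogram(df, ["clin"])
            nom_r = rs.build_nomogram(df, ["clin", "signature"])
            def cindex(nom, covs):
                lp = df[covs].to_numpy() @ np.array(
                    [nom.cox.coefficients[c] for c in covs]
                )
                return rs.harrell_cindex(lp, df["time_months"], df["event"])[0]
            wins += cindex(nom_r, ["clin", "signature"]) >= cindex(nom_c, ["clin"])
        assert wins >= 0.9 * n_reps


class TestCalibration:
    def test_well_calibrated_simulation(self):
        # predictions = true exponential survival at the horizon
        rng = np.random.default_rng(5)
        n = 2000
        lp = rng.standard_normal(n) * 0.7
        rate = 0.02 * np.exp(lp)
        t = rng.exponential(1 / rate)
        h = 24.0
        true_surv = np.exp(-rate * h)
        cal = rs.calibration_curve(pd.Series(true_surv), t, np.ones(n), h)
        assert (cal["predicted"] - cal["observed"]).abs().mean() < 0.05

    def test_constant_predictions_single_group(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(30, 50)
        with pytest.warns(UserWarning, match="single"):
            cal = rs.calibration_curve(pd.Series(np.full(50, 0.7)), t, np.ones(50), 12.0)
        assert len(cal) == 1

    def test_group_means_bracket_overall_km(self):
        rng = np.random.default_rng(7)
        n = 400
        lp = rng.standard_normal(n)
        t = rng.exponential(1 / (0.02 * np.exp(lp)))
        h = 24.0
        cal = rs.calibration_curve(pd.Series(-lp), t, np.ones(n), h)
        overall = rs.km_estimate(t, np.ones(n)).at(h)
        assert cal["observed"].min() - 1e-9 <= overall <= cal["observed"].max() + 1e-9


class TestDecisionCurve:
    def test_treat_all_closed_form_no_censoring(self):
        rng = np.random.default_rng(8)
        n = 300
        is_event = rng.random(n) < 0.3
        t = np.where(is_event, 10.0, 100.0)
        prev = is_event.mean()
        dca = rs.decision_curve(
            np.ones(n), t, is_event.astype(int), 36.0, [0.1, 0.3, 0.5]
        )
        for _, row in dca.iterrows():
            pt = row["threshold"]
            assert row["treat_all"] == pytest.approx(
                prev - (1 - prev) * pt / (1 - pt), abs=1e-12
            )
            assert row["net_benefit"] == pytest.approx(row["treat_all"], abs=1e-12)
            assert row["treat_none"] == 0.0

    def test_perfect_predictor_net_benefit_equals_prevalence(self):
        rng = np.random.default_rng(9)
        n = 200
        is_event = rng.random(n) < 0.4
        t = np.where(is_event, 5.0, 100.0)
        dca = rs.decision_curve(
            is_event.astype(float), t, is_event.astype(int), 36.0, [0.2, 0.5, 0.8]
        )
        assert np.allclose(dca["net_benefit"], is_event.mean(), atol=1e-12)

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(10)
        n = 150
        pred = rng.random(n)
        is_event = rng.random(n) < pred  # informative
        t = np.where(is_event, 12.0, 90.0)
        thresholds = [0.25, 0.5, 0.75]
        dca = rs.decision_curve(pred, t, is_event.astype(int), 36.0, thresholds)
        for pt, nb in zip(thresholds, dca["net_benefit"]):
            assert nb == pytest.approx(brute_net_benefit(pred, is_event, pt), abs=1e-9)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="strictly"):
            rs.decision_curve([0.5], [10.0], [1], 5.0, [1.0])


class TestReclassification:
    def test_identical_models_zero(self):
        rng = np.random.default_rng(11)
        pred = rng.random(50)
        t = rng.exponential(30, 50)
        with pytest.warns(UserWarning, match="no reclassification"):
            nri = rs.compute_nri(pred, pred.copy(), t, np.ones(50), 24.0)
        assert nri["nri"] == 0.0
        idi = rs.compute_idi(pred, pred.copy(), t, np.ones(50), 24.0)
        assert idi["idi"] == 0.0

    def test_four_subject_hand_count(self):
        # events: subjects 0, 1 (by t=36); non-events: 2, 3. Up moves: 0, 2.
        pred_old = np.array([0.2, 0.5, 0.3, 0.6])
        pred_new = np.array([0.6, 0.4, 0.5, 0.1])
        t = np.array([10.0, 20.0, 80.0, 90.0])
        e = np.array([1, 1, 0, 0])
        nri = rs.compute_nri(pred_old, pred_new, t, e, 36.0)
        # events: up 1/2, down 1/2 -> 0 ; non-events: down 1/2, up 1/2 -> 0
        assert nri["nri_events"] == pytest.approx(0.0)
        assert nri["nri_nonevents"] == pytest.approx(0.0)
        idi = rs.compute_idi(pred_old, pred_new, t, e, 36.0)
        slope_new = (0.6 + 0.4) / 2 - (0.5 + 0.1) / 2
        slope_old = (0.2 + 0.5) / 2 - (0.3 + 0.6) / 2
        assert idi["idi"] == pytest.approx(slope_new - slope_old, abs=1e-12)

    def test_informative_model_beats_noise(self):
        nris = []
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            n = 1000
            risk = rng.random(n)
            t_event = rng.exponential(1 / (0.05 * risk + 0.005))
            c = np.minimum(rng.exponential(100, n), 60)
            t = np.minimum(t_event, c)
            e = (t_event <= c).astype(int)
            nri = rs.compute_nri(rng.random(n), risk, t, e, 36.0)
            nris.append(nri["nri"])
        res = __import__("scipy.stats", fromlist=["ttest_1samp"]).ttest_1samp(
            nris, 0, alternative="greater"
        )
        assert res.pvalue < 0.01

    def test_noise_predictor_adds_no_idi(self):
        rng = np.random.default_rng(12)
        n = 2000
        base = rng.random(n)
        t = rng.exponential(30, n)
        e = np.ones(n, dtype=int)
        noisy = np.clip(base + rng.normal(0, 0.01, n), 0, 1)
        idi = rs.compute_idi(base, noisy, t, e, 24.0)
        assert abs(idi["idi"]) < 0.02

    def test_antisymmetry_under_model_swap(self):
        rng = np.random.default_rng(13)
        n = 200
        a, b = rng.random(n), rng.random(n)
        t = rng.exponential(30, n)
        e = rng.integers(0, 2, n)
        nri_ab = rs.compute_nri(a, b, t, e, 24.0)["nri"]
        nri_ba = rs.compute_nri(b, a, t, e, 24.0)["nri"]
        assert nri_ab == pytest.approx(-nri_ba, abs=1e-12)
        idi_ab = rs.compute_idi(a, b, t, e, 24.0)["idi"]
        idi_ba = rs.compute_idi(b, a, t, e, 24.0)["idi"]
        assert idi_ab == pytest.approx(-idi_ba, abs=1e-12)
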