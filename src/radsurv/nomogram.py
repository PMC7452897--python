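"""Nomograms, calibration, decision curves and reclassification metrics.

A nomogram is a point-scale rendering of a Cox model: each covariate's
contribution is mapped to 0..100 points (100 for the largest absolute
contribution range) and total points map back to the linear predictor,
so predicted survival from points equals the Cox prediction exactly.
Survival probabilities use the Breslow baseline: S(t|x) = S0(t)^exp(lp)
with S0 the baseline at covariate value zero.

NRI and IDI are the category-free (continuous) variants at a fixed
horizon; under censoring, event status at the horizon is weighted by
the Kaplan-Meier survival of the cohort (subjects censored before the
horizon contribute fractionally via P(event by t | alive at censoring)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import CoxFit, fit_cox, km_estimate

__all__ = [
    "NomogramModel",
    "build_nomogram",
    "predict_dmfs",
    "calibration_curve",
    "decision_curve",
    "compute_nri",
    "compute_idi",
]


@dataclass
class NomogramModel:
    cox: CoxFit
    covariates: list[str]
    #: per-covariate (points per unit, offset) so points = ppu * (x - x_min)
    point_scale: dict[str, tuple[float, float]]
    #: linear predictor per nomogram point (signed by coefficient)
    lp_per_point: float
    lp_offset: float  # lp at zero total points
    baseline_survival: dict[float, float]  # S0(t) at the fitted horizons

    def total_points(self, row: pd.Series) -> float:
        return float(
            sum(
                ppu * (float(row[c]) - x0)
                for c, (ppu, x0) in self.point_scale.items()
            )
        )

    def linear_predictor(self, row: pd.Series) -> float:
        return float(
            sum(self.cox.coefficients[c] * float(row[c]) for c in self.covariates)
        )


def build_nomogram(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time_months",
    event_col: str = "event",
    horizons: tuple[float, ...] = (12.0, 24.0, 36.0),
) -> NomogramModel:
    """Fit a Cox model and its point-scale / baseline-survival rendering."""
    cox = fit_cox(df, duration_col, event_col, covariates)
    beta = cox.coefficients
    ranges = {}
    for c in covariates:
        lo, hi = df[c].min(), df[c].max()
        ranges[c] = abs(beta[c]) * (hi - lo)
    widest = max(ranges.values())
    if widest == 0:
        raise ValueError("all covariates are constant in effect range")
    lp_per_point = widest / 100.0  # |lp| spanned by one point of the widest axis
    point_scale = {}
    for c in covariates:
        lo = df[c].min() if beta[c] >= 0 else df[c].max()
        ppu = beta[c] / lp_per_point
        point_scale[c] = (float(ppu), float(lo))
    # offset: lp when every covariate sits at its zero-point anchor
    lp_offset = float(sum(beta[c] * point_scale[c][1] for c in covariates))

    # Breslow baseline at x = 0 from the lifelines baseline (held at the mean)
    cph = cox._fitter
    mean_lp = float(
        sum(beta[c] * cph._norm_mean[c] for c in covariates)
    )
    baseline = {}
    bch = cox.baseline_cumhaz
    for h in horizons:
        idx = bch.index.searchsorted(h, side="right") - 1
        h0 = float(bch.iloc[idx]) if idx >= 0 else 0.0
        baseline[float(h)] = float(np.exp(-h0 * np.exp(-mean_lp)))
    return NomogramModel(
        cox=cox,
        covariates=list(covariates),
        point_scale=point_scale,
        lp_per_point=float(lp_per_point),
        lp_offset=lp_offset,
        baseline_survival=baseline,
    )


def predict_dmfs(
    model: NomogramModel, row: pd.Series | pd.DataFrame, horizon: float
) -> float | np.ndarray:
    """P(event-free at `horizon`) = S0(horizon)^exp(lp)."""
    if float(horizon) not in model.baseline_survival:
        raise ValueError(
            f"horizon {horizon} not fitted; available: {sorted(model.baseline_survival)}"
        )
    s0 = model.baseline_survival[float(horizon)]
    if isinstance(row, pd.DataFrame):
        lp = row[model.covariates].to_numpy(dtype=float) @ np.array(
            [model.cox.coefficients[c] for c in model.covariates]
        )
        return s0 ** np.exp(np.clip(lp, -700, 700))
    return float(s0 ** np.exp(np.clip(model.linear_predictor(row), -700, 700)))


# ---------------------------------------------------------------------------
# calibration

def calibration_curve(
    predictions: pd.Series,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float,
    n_groups: int = 5,
) -> pd.DataFrame:
    """Quantile-binned predicted survival vs observed KM at the horizon."""
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    preds = np.asarray(predictions, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.unique(preds).size == 1:
        warnings.warn("all predictions equal: single calibration group", stacklevel=2)
        bins = np.zeros(len(preds), dtype=int)
        n_groups = 1
    else:
        q = pd.qcut(preds, n_groups, labels=False, duplicates="drop")
        bins = np.asarray(q, dtype=int)
        n_groups = bins.max() + 1
    rows = []
    for g in range(n_groups):
        sel = bins == g
        km = km_estimate(time[sel], event[sel])
        s = km.at(horizon)
        lo_idx = np.searchsorted(km.times, horizon, side="right") - 1
        ci_lo = float(km.ci_lower[lo_idx]) if lo_idx >= 0 else 1.0
        ci_hi = float(km.ci_upper[lo_idx]) if lo_idx >= 0 else 1.0
        rows.append(
            {
                "group": g,
                "n": int(sel.sum()),
                "predicted": float(preds[sel].mean()),
                "observed": s,
                "ci_lower": ci_lo,
                "ci_upper": ci_hi,
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# decision curves

def _km_event_prob(time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    """P(event by horizon) via KM, valid under censoring."""
    if len(time) == 0:
        return 0.0
    return 1.0 - km_estimate(time, event).at(horizon)


def decision_curve(
    predictions_of_event: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float,
    thresholds: np.ndarray,
) -> pd.DataFrame:
    """Net benefit NB(pt) = TP/n - FP/n * pt/(1-pt) at each threshold.

    Event status at the horizon is estimated by KM within the treated
    (prediction >= pt) subgroup, which reduces to plain 2x2 counting
    when there is no censoring before the horizon.  Includes treat-all
    and treat-none (identically 0) references.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds >= 1) or np.any(thresholds <= 0):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    preds = np.asarray(predictions_of_event, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(preds)
    prev_all = _km_event_prob(time, event, horizon)
    rows = []
    for pt in thresholds:
        odds = pt / (1.0 - pt)
        sel = preds >= pt
        frac = sel.mean()
        if sel.any():
            p_event = _km_event_prob(time[sel], event[sel], horizon)
            nb = frac * p_event - frac * (1.0 - p_event) * odds
        else:
            nb = 0.0
        nb_all = prev_all - (1.0 - prev_all) * odds
        rows.append(
            {"threshold": pt, "net_benefit": nb, "treat_all": nb_all, "treat_none": 0.0}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NRI / IDI

def _horizon_weights(
    time: np.ndarray, event: np.ndarray, horizon: float
) -> tuple[np.ndarray, np.ndarray]:
    """(w_event, w_nonevent) per subject at the horizon, KM-weighted.

    Observed events by the horizon weigh 1 as events; subjects followed
    beyond the horizon weigh 1 as non-events; subjects censored before
    it split as P(T <= h | T > c) = 1 - S(h)/S(c) from the overall KM.
    """
    km = km_estimate(time, event)
    s_h = km.at(horizon)
    w_e = np.zeros(len(time))
    w_ne = np.zeros(len(time))
    for i, (t, e) in enumerate(zip(time, event)):
        if t <= horizon and e:
            w_e[i] = 1.0
        elif t > horizon:
            w_ne[i] = 1.0
        else:  # censored before the horizon
            s_c = km.at(t)
            p = 1.0 - s_h / s_c if s_c > 0 else 1.0
            w_e[i] = p
            w_ne[i] = 1.0 - p
    return w_e, w_ne


def compute_nri(
    pred_old: np.ndarray,
    pred_new: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float = 36.0,
) -> dict[str, float]:
    """Category-free net reclassification improvement at the horizon.

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) -
    P(up|non-event)] where up/down are increases/decreases of predicted
    event risk from the old to the new model.
    """
    pred_old = np.asarray(pred_old, dtype=float)
    pred_new = np.asarray(pred_new, dtype=float)
    if pred_old.shape != pred_new.shape:
        raise ValueError("prediction sets must cover the same subjects")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    up = pred_new > pred_old
    down = pred_new < pred_old
    if not up.any() and not down.any():
        warnings.warn("no reclassification moves: NRI = 0", stacklevel=2)
        return {"nri": 0.0, "nri_events": 0.0, "nri_nonevents": 0.0, "horizon": horizon}
    w_e, w_ne = _horizon_weights(time, event, horizon)
    if w_e.sum() == 0 or w_ne.sum() == 0:
        raise ValueError("no (weighted) events or non-events at this horizon")
    nri_e = float((w_e * up).sum() / w_e.sum() - (w_e * down).sum() / w_e.sum())
    nri_ne = float((w_ne * down).sum() / w_ne.sum() - (w_ne * up).sum() / w_ne.sum())
    return {
        "nri": nri_e + nri_ne,
        "nri_events": nri_e,
        "nri_nonevents": nri_ne,
        "horizon": horizon,
    }


def compute_idi(
    pred_old: np.ndarray,
    pred_new: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float = 36.0,
) -> dict[str, float]:
    """Integrated discrimination improvement at the horizon.

    The difference in discrimination slopes: (mean predicted event risk
    among events - among non-events), new model minus old, with the
    same KM horizon weights as the NRI.
    """
    pred_old = np.asarray(pred_old, dtype=float)
    pred_new = np.asarray(pred_new, dtype=float)
    if pred_old.shape != pred_new.shape:
        raise ValueError("prediction sets must cover the same subjects")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    w_e, w_ne = _horizon_weights(time, event, horizon)
    if w_e.sum() == 0 or w_ne.sum() == 0:
        raise ValueError("no (weighted) events or non-events at this horizon")

    def slope(pred: np.ndarray) -> float:
        return float((w_e * pred).sum() / w_e.sum() - (w_ne * pred).sum() / w_ne.sum())

    return {"idi": slope(pred_new) - slope(pred_old), "horizon": horizon}
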