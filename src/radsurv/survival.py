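"""Survival machinery: Kaplan-Meier, log-rank, Cox PH, time-dependent
AUC, Harrell's C-index and baseline-table comparisons.

Standard estimators are delegated to lifelines (KM, log-rank, Cox with
Efron ties) and scikit-survival (IPCW cumulative/dynamic AUC); the
concordance index is computed in-package because a confidence interval
is needed alongside the point estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

__all__ = [
    "KMCurve",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "fit_cox",
    "time_dependent_auc",
    "harrell_cindex",
    "compare_baselines",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def at(self, t: float) -> float:
        """S(t): right-continuous step-function evaluation."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_times(time: np.ndarray) -> np.ndarray:
    time = np.asarray(time, dtype=float)
    if np.any(time < 0):
        raise ValueError("negative survival times")
    return time


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier estimate; events precede censorings at tied times."""
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_survival_function_
    times = sf.index.to_numpy(dtype=float)
    return KMCurve(
        times=times,
        survival=sf.iloc[:, 0].to_numpy(),
        at_risk=kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
    )


def logrank_test(
    time_a, event_a, time_b, event_b
) -> tuple[float, float]:
    """Two-sided two-group log-rank test (1 df chi-square)."""
    time_a, time_b = _check_times(time_a), _check_times(time_b)
    event_a = np.asarray(event_a, dtype=int)
    event_b = np.asarray(event_b, dtype=int)
    if len(time_a) == 0 or len(time_b) == 0:
        raise ValueError("both groups must be non-empty")
    if event_a.sum() + event_b.sum() == 0:
        warnings.warn("no events in either group: log-rank p = 1", stacklevel=2)
        return 0.0, 1.0
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model (Efron ties)."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    log_likelihood: float
    baseline_cumhaz: pd.Series  # Breslow estimate at the covariate mean
    _fitter: CoxPHFitter = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "HR_lower95": self.ci_lower,
                "HR_upper95": self.ci_upper,
                "p": self.p_values,
            }
        )


def fit_cox(
    df: pd.DataFrame,
    duration_col: str = "time_months",
    event_col: str = "event",
    covariates: list[str] | None = None,
) -> CoxFit:
    """Cox partial-likelihood fit with Efron tie handling.

    Raises on constant covariates and names the offending covariate on
    non-convergence (typically separation).
    """
    covariates = covariates or [
        c for c in df.columns if c not in (duration_col, event_col)
    ]
    data = df[[duration_col, event_col, *covariates]].copy()
    for c in covariates:
        if data[c].nunique() <= 1:
            raise ValueError(f"constant covariate {c!r}")
    n_events = int(data[event_col].sum())
    if n_events < len(covariates):
        warnings.warn(
            f"only {n_events} events for {len(covariates)} covariates", stacklevel=2
        )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(
            f"Cox fit failed to converge (covariates {covariates}): {err}"
        ) from err
    summ = cph.summary
    return CoxFit(
        coefficients=cph.params_,
        covariance=cph.variance_matrix_,
        hazard_ratios=np.exp(cph.params_),
        ci_lower=np.exp(summ["coef lower 95%"]),
        ci_upper=np.exp(summ["coef upper 95%"]),
        p_values=summ["p"],
        log_likelihood=float(cph.log_likelihood_),
        baseline_cumhaz=cph.baseline_cumulative_hazard_.iloc[:, 0],
        _fitter=cph,
    )


def time_dependent_auc(
    marker: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizons: tuple[float, ...] = (12.0, 24.0, 36.0),
) -> dict[float, float]:
    """Cumulative-case / dynamic-control AUC(t) with IPCW weighting.

    Cases at horizon t are subjects with an event by t; controls are
    those event-free beyond t; censoring is weighted by the inverse of
    the Kaplan-Meier censoring distribution.
    """
    marker = np.asarray(marker, dtype=float)
    time = _check_times(time)
    event = np.asarray(event, dtype=bool)
    out: dict[float, float] = {}
    max_follow = time.max()
    y = Surv.from_arrays(event=event, time=time)
    for h in horizons:
        if h >= max_follow:
            raise ValueError(f"horizon {h} beyond follow-up (max {max_follow:.1f})")
        if not np.any(event & (time <= h)):
            raise ValueError(f"no events observed by horizon {h}")
        auc, _ = cumulative_dynamic_auc(y, y, marker, [h])
        out[h] = float(auc[0])
    return out


def harrell_cindex(
    marker: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Harrell's concordance index with a 95% CI.

    Usable pairs: the subject with the shorter observed time had an
    event (tied event times are not comparable).  Marker ties count
    1/2.  The CI is a leave-one-subject-out jackknife on the
    concordance ratio — an asymptotic normal interval.
    """
    marker = np.asarray(marker, dtype=float)
    time = _check_times(time)
    event = np.asarray(event, dtype=bool)
    n = len(marker)
    # comparable[i, j]: i has the event and strictly shorter time than j
    shorter = time[:, None] < time[None, :]
    comparable = shorter & event[:, None]
    higher = marker[:, None] > marker[None, :]
    tied = marker[:, None] == marker[None, :]
    conc = comparable & higher
    part = comparable & tied
    P = comparable.sum()
    if P == 0:
        raise ValueError("no usable pairs (all times tied or no events)")
    C = conc.sum() + 0.5 * part.sum()
    c = C / P
    # jackknife over subjects
    pair_c = conc + 0.5 * part  # numerator contribution of each ordered pair
    C_i = pair_c.sum(axis=0) + pair_c.sum(axis=1)
    P_i = comparable.sum(axis=0) + comparable.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (C - C_i) / (P - P_i)
    loo = loo[np.isfinite(loo)]
    if len(loo) > 1:
        se = np.sqrt((len(loo) - 1) / len(loo) * ((loo - loo.mean()) ** 2).sum())
    else:
        se = 0.0
    return float(c), (float(c - 1.96 * se), float(c + 1.96 * se))


def compare_baselines(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    variable_types: dict[str, str],
) -> pd.DataFrame:
    """Between-cohort baseline comparison.

    Continuous variables: two-sample t test when both samples pass a
    Shapiro normality screen at 0.05, Mann-Whitney U otherwise.
    Categorical variables: chi-square unless any expected cell count is
    below 5, then Fisher's exact test (2x2).  All two-sided.
    """
    rows = []
    for var, kind in variable_types.items():
        a, b = table_a[var].dropna(), table_b[var].dropna()
        if kind == "continuous":
            normal = (
                len(a) >= 3
                and len(b) >= 3
                and stats.shapiro(a).pvalue > 0.05
                and stats.shapiro(b).pvalue > 0.05
            )
            if normal:
                test, p = "t", stats.ttest_ind(a, b).pvalue
            else:
                test, p = "mann-whitney", stats.mannwhitneyu(
                    a, b, alternative="two-sided"
                ).pvalue
        elif kind == "categorical":
            levels = sorted(set(a) | set(b))
            if not levels:
                raise ValueError(f"{var}: no category levels present")
            counts = np.array(
                [[np.sum(a == l) for l in levels], [np.sum(b == l) for l in levels]]
            )
            counts = counts[:, counts.sum(axis=0) > 0]
            chi2 = stats.chi2_contingency(counts, correction=False)
            if (chi2.expected_freq < 5).any() and counts.shape == (2, 2):
                test, p = "fisher", stats.fisher_exact(counts)[1]
            else:
                test, p = "chi2", chi2.pvalue
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var}")
        rows.append({"variable": var, "test": test, "p": float(p)})
    return pd.DataFrame(rows).set_index("variable")
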