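"""Coarse-to-fine feature selection and the LASSO-Cox radiomic signature.

The selection cascade reduces ~1240 features to a handful:

1. univariate Cox screen — one single-covariate proportional-hazards
   fit per feature (Efron ties), Wald p-value;
2. coarse filter — features ranked by p ascending; keep those with
   p < 0.1 that are also in the top 20% of all features;
3. correlation pruning — greedily break feature pairs with |r| > 0.6,
   removing the member with the larger mean absolute correlation;
4. LASSO-Cox — L1-penalized Cox regression, penalty chosen by k-fold
   cross-validated partial-likelihood deviance; nonzero-coefficient
   features form the signature.

The signature score is the penalized linear predictor; the primary
cohort's median score is the portable high/low cutoff applied
unchanged to validation cohorts.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "SignatureModel",
    "ScreeningResult",
    "normalize_features",
    "univariate_cox_screen",
    "coarse_filter",
    "correlation_prune",
    "fit_lasso_cox",
    "score",
    "fit_cutoff",
    "stratify",
    "build_signature",
]


# ---------------------------------------------------------------------------
# normalization

def normalize_features(
    table: pd.DataFrame, stats_: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score features; validation cohorts reuse primary-cohort stats.

    With ``stats_`` None the per-feature mean/sd are fit on the given
    (primary) table and returned; otherwise the stored stats are
    applied without refitting, which is what makes the median cutoff
    portable across cohorts.
    """
    if stats_ is None:
        mean = table.mean()
        sd = table.std(ddof=0)
        bad = sd[sd == 0].index.tolist()
        if bad:
            raise ValueError(f"constant features cannot be normalized: {bad[:5]}")
        stats_ = pd.DataFrame({"mean": mean, "sd": sd})
    else:
        missing = [c for c in table.columns if c not in stats_.index]
        if missing:
            raise KeyError(f"features absent from normalization stats: {missing[:5]}")
    normed = (table - stats_.loc[table.columns, "mean"]) / stats_.loc[
        table.columns, "sd"
    ]
    return normed, stats_


# ---------------------------------------------------------------------------
# univariate Cox screen (vectorized across features)

def _cox_univariate_many(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton-Raphson single-covariate Cox fits for every column of X.

    Efron handling of tied event times.  Returns (beta, se, converged).
    All features are iterated simultaneously; the per-iteration loop
    runs over distinct event times only.
    """
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    Xs = X[order]
    ts = time[order]
    es = event[order].astype(bool)

    # event-time groups: (start index in sorted array, indices of tied events)
    groups: list[tuple[int, np.ndarray]] = []
    ev_times = np.unique(ts[es])
    for t in ev_times:
        start = int(np.searchsorted(ts, t, side="left"))
        d_idx = np.nonzero((ts == t) & es)[0]
        groups.append((start, d_idx))

    beta = np.zeros(p)
    active = np.ones(p, dtype=bool)
    info = np.full(p, np.nan)
    for _ in range(max_iter):
        eta = np.clip(Xs * beta[None, :], -200, 200)
        W = np.exp(eta)
        WX = W * Xs
        WXX = WX * Xs
        suf0 = np.cumsum(W[::-1], axis=0)[::-1]
        suf1 = np.cumsum(WX[::-1], axis=0)[::-1]
        suf2 = np.cumsum(WXX[::-1], axis=0)[::-1]
        grad = np.zeros(p)
        hess = np.zeros(p)
        for start, d_idx in groups:
            d = len(d_idx)
            s0r, s1r, s2r = suf0[start], suf1[start], suf2[start]
            grad += Xs[d_idx].sum(axis=0)
            if d == 1:
                mu = s1r / s0r
                grad -= mu
                hess -= s2r / s0r - mu**2
            else:
                s0d = W[d_idx].sum(axis=0)
                s1d = WX[d_idx].sum(axis=0)
                s2d = WXX[d_idx].sum(axis=0)
                for l in range(d):
                    f = l / d
                    c0 = s0r - f * s0d
                    c1 = s1r - f * s1d
                    c2 = s2r - f * s2d
                    mu = c1 / c0
                    grad -= mu
                    hess -= c2 / c0 - mu**2
        cur_info = -hess
        ok = active & (cur_info > 1e-12)
        step = np.zeros(p)
        step[ok] = grad[ok] / cur_info[ok]
        step = np.clip(step, -5, 5)
        beta[ok] += step[ok]
        info[ok] = cur_info[ok]
        active = ok & (np.abs(step) > 1e-9)
        if not active.any():
            break
    converged = (~active) & np.isfinite(info) & (info > 1e-12) & (np.abs(beta) < 50)
    se = np.where(converged, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.nan)
    return beta, se, converged


def univariate_cox_screen(
    features: pd.DataFrame, survival: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature univariate Cox (beta, p); screen for the coarse filter.

    Degenerate (constant) or non-converging features are recorded with
    p = 1 and a warning, which effectively drops them downstream.
    """
    time = survival["time_months"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events for the univariate screen")
    X = features.to_numpy(dtype=float)
    sd = X.std(axis=0)
    degenerate = sd == 0
    X_fit = np.where(degenerate[None, :], 0.0, X)
    beta, se, converged = _cox_univariate_many(X_fit, time, event)
    z = np.where(converged, beta / se, 0.0)
    p = np.where(converged, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    beta = np.where(converged, beta, 0.0)
    p = np.where(degenerate, 1.0, p)
    n_bad = int(degenerate.sum() + (~converged & ~degenerate).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} feature(s) degenerate or non-converged; recorded with p=1",
            stacklevel=2,
        )
    return pd.DataFrame({"beta": beta, "p": p}, index=features.columns)


# ---------------------------------------------------------------------------
# coarse filter and correlation pruning

def coarse_filter(
    pvalues: pd.Series,
    fraction: float = 0.20,
    alpha: float = 0.1,
    mode: str = "intersection",
) -> list[str]:
    """Keep features ranked in the top ``fraction`` by p with p < alpha.

    ``mode='intersection'`` (default) caps at ``ceil(fraction * total
    feature count)`` and intersects with {p < alpha}; ties in p are
    broken by the stable input (catalog) order.
    ``mode='within_significant'`` instead takes the top fraction of the
    p < alpha subset.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    significant = pvalues[pvalues < alpha]
    if mode == "intersection":
        cap = math.ceil(fraction * len(pvalues))
        ranked = pvalues.sort_values(kind="stable").index[:cap]
        return [f for f in pvalues.index if f in set(ranked) and pvalues[f] < alpha]
    if mode == "within_significant":
        cap = math.ceil(fraction * len(significant))
        ranked = significant.sort_values(kind="stable").index[:cap]
        return [f for f in pvalues.index if f in set(ranked)]
    raise ValueError(f"unknown mode {mode!r}")


def correlation_prune(table: pd.DataFrame, cutoff: float = 0.6) -> list[str]:
    """Greedy Pearson-correlation pruning.

    While any retained pair has |r| > cutoff: take the pair with the
    largest |r| (ties broken by lexicographic name order) and drop the
    member with the larger mean absolute correlation against the
    currently retained set (ties drop the later input-order name).
    The survivors satisfy max off-diagonal |r| <= cutoff.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        return cols
    if len(table) < 3:
        raise ValueError("need at least 3 samples for correlation pruning")
    sd = table.std(ddof=0)
    const = sd[sd == 0].index.tolist()
    if const:
        warnings.warn(
            f"constant feature(s) {const[:3]}: correlations defined as 0", stacklevel=2
        )
    R = table.corr().abs().fillna(0.0)
    np.fill_diagonal(R.values, 0.0)
    retained = list(cols)
    order = {c: i for i, c in enumerate(cols)}
    while len(retained) > 1:
        sub = R.loc[retained, retained]
        m = sub.to_numpy()
        max_r = m.max()
        if max_r <= cutoff:
            break
        ii, jj = np.nonzero(m == max_r)
        pairs = sorted(
            {tuple(sorted((retained[i], retained[j]))) for i, j in zip(ii, jj) if i < j}
        )
        a, b = pairs[0]
        mean_a = sub.loc[a].drop(a).mean()
        mean_b = sub.loc[b].drop(b).mean()
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = a if order[a] > order[b] else b
        retained.remove(drop)
    return retained


# ---------------------------------------------------------------------------
# LASSO-Cox

def _breslow_partial_loglik(
    lp: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    order = np.argsort(time, kind="stable")
    lp_s, t_s, e_s = lp[order], time[order], event[order].astype(bool)
    rev_lse = np.logaddexp.accumulate(lp_s[::-1])[::-1]
    starts = np.searchsorted(t_s, t_s, side="left")
    return float(np.sum(lp_s[e_s] - rev_lse[starts[e_s]]))


@dataclass
class SignatureModel:
    """A fitted radiomic signature.

    score(x) = sum_k coefficient_k * (x_k - mean_k) / sd_k over the
    selected features; patients with score > cutoff are high risk.
    """

    selected_features: list[str]
    coefficients: np.ndarray
    normalization_stats: pd.DataFrame  # index = feature, columns mean/sd
    lambda_: float
    seed: int
    cutoff: float | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.selected_features) < 1:
            raise ValueError("a signature needs at least one feature")
        if (self.normalization_stats["sd"] <= 0).any():
            raise ValueError("normalization sds must be positive")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected_features": self.selected_features,
            "coefficients": self.coefficients.tolist(),
            "normalization": {
                f: [float(self.normalization_stats.loc[f, "mean"]),
                    float(self.normalization_stats.loc[f, "sd"])]
                for f in self.selected_features
            },
            "lambda": self.lambda_,
            "seed": self.seed,
            "cutoff": self.cutoff,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        payload = json.loads(Path(path).read_text())
        stats_ = pd.DataFrame(
            {
                f: {"mean": m, "sd": s}
                for f, (m, s) in payload["normalization"].items()
            }
        ).T
        return cls(
            selected_features=payload["selected_features"],
            coefficients=np.asarray(payload["coefficients"]),
            normalization_stats=stats_,
            lambda_=payload["lambda"],
            seed=payload["seed"],
            cutoff=payload["cutoff"],
        )


@dataclass
class ScreeningResult:
    """Survivors of each coarse-to-fine stage (nested sets)."""

    screen: pd.DataFrame  # per-feature beta, p
    coarse_set: list[str]
    pruned_set: list[str]
    selected: list[str]

    def __post_init__(self) -> None:
        all_f = set(self.screen.index)
        assert set(self.selected) <= set(self.pruned_set) <= set(
            self.coarse_set
        ) <= all_f, "selection stages must be nested"


def fit_lasso_cox(
    features: pd.DataFrame,
    survival: pd.DataFrame,
    normalization_stats: pd.DataFrame,
    n_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "1se",
    alphas: np.ndarray | None = None,
) -> SignatureModel:
    """L1-penalized Cox fit with CV-deviance penalty selection.

    ``features`` must already be normalized (the stats are stored in
    the returned model for scoring new cohorts).  The penalty grid is
    the coxnet path on the full data; cross-validated Breslow
    partial-likelihood deviance over seeded k-fold splits selects the
    penalty.  ``lambda_rule='1se'`` (default) takes the largest
    penalty within one standard error of the minimum — the sparser
    conventional glmnet rule, which keeps false-positive features in
    check; ``'min'`` takes the deviance minimum itself.
    """
    time = survival["time_months"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    X = features.to_numpy(dtype=float)
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    if alphas is None:
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=60, max_iter=200000
        )
    else:
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=np.asarray(alphas, dtype=float), max_iter=200000
        )
    path.fit(X, y)
    alphas = path.alphas_

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros((n_folds, len(alphas)))
    for k, (tr, te) in enumerate(kf.split(X)):
        if event[te].sum() == 0 or event[tr].sum() == 0:
            dev[k] = np.nan
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, max_iter=200000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(X[tr], y[tr])
        fitted = list(m.alphas_)
        for a_idx, a in enumerate(alphas):
            if a in fitted:
                coef = m.coef_[:, fitted.index(a)]
            else:  # path truncated on this fold: nearest fitted alpha
                coef = m.coef_[:, int(np.argmin(np.abs(np.array(fitted) - a)))]
            lp_te = X[te] @ coef
            dev[k, a_idx] = -2.0 * _breslow_partial_loglik(lp_te, time[te], event[te])
    mean_dev = np.nanmean(dev, axis=0)
    best = int(np.nanargmin(mean_dev))
    if lambda_rule == "1se":
        se_dev = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(n_folds)
        limit = mean_dev[best] + se_dev[best]
        # alphas_ is descending: prefer the largest penalty within 1 SE
        # that still retains at least one feature
        candidates = np.nonzero(mean_dev <= limit)[0]
        nonzero_counts = (path.coef_ != 0).sum(axis=0)
        with_features = candidates[nonzero_counts[candidates] > 0]
        best = int(with_features[0]) if with_features.size else int(candidates[0])
    elif lambda_rule != "min":
        raise ValueError("lambda_rule must be '1se' or 'min'")
    lam = float(alphas[best])
    coef = path.coef_[:, best]
    nz = np.nonzero(coef)[0]
    if nz.size == 0:
        raise ValueError(
            "all LASSO-Cox coefficients are zero at the selected penalty; "
            "refit with a smaller lambda grid (alpha_min_ratio)"
        )
    selected = [features.columns[i] for i in nz]
    return SignatureModel(
        selected_features=selected,
        coefficients=coef[nz],
        normalization_stats=normalization_stats.loc[selected],
        lambda_=lam,
        seed=seed,
    )


def score(model: SignatureModel, features: pd.DataFrame) -> pd.Series:
    """Per-patient signature value from *raw* (unnormalized) features."""
    missing = [f for f in model.selected_features if f not in features.columns]
    if missing:
        raise KeyError(f"features required by the signature are missing: {missing}")
    sub = features[model.selected_features]
    normed, _ = normalize_features(sub, model.normalization_stats)
    values = normed.to_numpy(dtype=float) @ model.coefficients
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite signature scores")
    return pd.Series(values, index=features.index, name="radiomic_signature")


def fit_cutoff(model: SignatureModel, primary_scores: pd.Series) -> SignatureModel:
    """Fix the high/low cutoff at the primary cohort's median score."""
    model.cutoff = float(np.median(primary_scores))
    return model


def stratify(model: SignatureModel, scores: pd.Series) -> pd.Series:
    """High/low risk groups; score > cutoff is high, ties go to low."""
    if model.cutoff is None:
        raise ValueError("cutoff not set: fit it on the primary cohort first")
    return pd.Series(
        np.where(scores > model.cutoff, "high", "low"),
        index=scores.index,
        name="risk_group",
    )


def build_signature(
    features: pd.DataFrame,
    survival: pd.DataFrame,
    fraction: float = 0.20,
    alpha: float = 0.1,
    corr_cutoff: float = 0.6,
    n_folds: int = 10,
    seed: int = 0,
    coarse_mode: str = "intersection",
    lambda_rule: str = "1se",
) -> tuple[SignatureModel, ScreeningResult]:
    """Run the full coarse-to-fine cascade on the primary cohort."""
    normed, stats_ = normalize_features(features)
    screen = univariate_cox_screen(normed, survival)
    coarse = coarse_filter(screen["p"], fraction=fraction, alpha=alpha, mode=coarse_mode)
    if not coarse:
        raise ValueError("coarse filter retained no features (all p >= alpha)")
    pruned = correlation_prune(normed[coarse], cutoff=corr_cutoff)
    model = fit_lasso_cox(
        normed[pruned], survival, stats_, n_folds=n_folds, seed=seed,
        lambda_rule=lambda_rule,
    )
    model = fit_cutoff(model, score(model, features))
    result = ScreeningResult(
        screen=screen, coarse_set=coarse, pruned_set=pruned, selected=model.selected_features
    )
    return model, result
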