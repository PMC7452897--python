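"""Treatment-by-biomarker interaction analysis.

Reproduces the subgroup chemotherapy-efficacy table: for each
pathological-stage level crossed with the high/low radiomic-signature
group, the chemotherapy-vs-no-chemotherapy hazard ratio with CI and
log-rank p, plus a Wald interaction p from a Cox model with main
effects and a product term fitted within the stage level.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .survival import fit_cox, logrank_test

__all__ = ["interaction_test", "subgroup_efficacy_table"]


def _as_numeric(series: pd.Series) -> pd.Series:
    """Binary/ordinal coding of a possibly categorical factor."""
    if series.dtype.kind in "ifb":
        return series.astype(float)
    levels = sorted(series.astype(str).unique())
    return series.astype(str).map({l: i for i, l in enumerate(levels)}).astype(float)


def interaction_test(
    df: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> float:
    """Wald p-value of the product term in a Cox model a + b + a*b."""
    a = _as_numeric(df[factor_a])
    b = _as_numeric(df[factor_b])
    for name, col in ((factor_a, a), (factor_b, b)):
        if col.nunique() <= 1:
            raise ValueError(f"factor {name!r} does not vary within the data")
    cells = pd.crosstab(a, b)
    if (cells == 0).any().any():
        empty = [
            (i, j) for i in cells.index for j in cells.columns if cells.loc[i, j] == 0
        ]
        raise ValueError(f"empty {factor_a} x {factor_b} cell(s): {empty}")
    work = pd.DataFrame(
        {
            duration_col: df[duration_col].to_numpy(dtype=float),
            event_col: df[event_col].to_numpy(dtype=int),
            factor_a: a.to_numpy(),
            factor_b: b.to_numpy(),
            "interaction": (a * b).to_numpy(),
        }
    )
    fit = fit_cox(work, duration_col, event_col, [factor_a, factor_b, "interaction"])
    return float(fit.p_values["interaction"])


def _cell_hr(
    sub: pd.DataFrame, treatment_col: str, duration_col: str, event_col: str
) -> tuple[float, float, float, str]:
    """CT-vs-no-CT hazard ratio within a subgroup; NA with reason when
    undefined (an arm without events or a failed fit)."""
    treated = sub[sub[treatment_col] == 1]
    untreated = sub[sub[treatment_col] == 0]
    if len(treated) == 0 or len(untreated) == 0:
        return np.nan, np.nan, np.nan, "an arm is empty"
    if treated[event_col].sum() == 0 or untreated[event_col].sum() == 0:
        return np.nan, np.nan, np.nan, "no events in one arm"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_cox(sub, duration_col, event_col, [treatment_col])
    except (RuntimeError, ValueError) as err:
        return np.nan, np.nan, np.nan, f"Cox fit failed: {err}"
    return (
        float(fit.hazard_ratios[treatment_col]),
        float(fit.ci_lower[treatment_col]),
        float(fit.ci_upper[treatment_col]),
        "",
    )


def subgroup_efficacy_table(
    df: pd.DataFrame,
    signature_group_col: str = "risk_group",
    stage_variable: str = "all",
    treatment_col: str = "adjuvant_ct",
    duration_col: str = "time_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Chemotherapy-efficacy rows per stage level x high/low RS cell.

    ``stage_variable`` is ``'pT'``, ``'pN'`` or ``'all'`` (no stage
    stratification).  Each row carries treated/untreated counts, the
    within-cell CT hazard ratio with 95% CI, a two-sided log-rank p,
    and the stage level's RS-by-treatment interaction p.  Cells that
    cannot support an estimate are flagged, not dropped.
    """
    if stage_variable not in ("pT", "pN", "all"):
        raise ValueError("stage_variable must be 'pT', 'pN' or 'all'")
    work = df.copy()
    work[treatment_col] = _as_numeric(work[treatment_col])
    strata = (
        [("all", work)]
        if stage_variable == "all"
        else [
            (str(lev), work[work[stage_variable] == lev])
            for lev in sorted(work[stage_variable].astype(str).unique())
        ]
    )
    rows = []
    for level, stratum in strata:
        stratum = stratum if stage_variable == "all" else work[
            work[stage_variable].astype(str) == level
        ]
        try:
            p_int = interaction_test(
                stratum, signature_group_col, treatment_col, duration_col, event_col
            )
        except (ValueError, RuntimeError) as err:
            p_int, int_note = np.nan, str(err)
        else:
            int_note = ""
        for rs in ("high", "low"):
            cell = stratum[stratum[signature_group_col] == rs]
            n_ct = int((cell[treatment_col] == 1).sum())
            n_noct = int((cell[treatment_col] == 0).sum())
            flag = ""
            if min(n_ct, n_noct) < 2:
                flag = "fewer than 2 subjects in an arm"
            hr, lo, hi, hr_note = _cell_hr(cell, treatment_col, duration_col, event_col)
            if n_ct > 0 and n_noct > 0 and (
                cell[cell[treatment_col] == 1][event_col].sum()
                + cell[cell[treatment_col] == 0][event_col].sum()
                > 0
            ):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, p_lr = logrank_test(
                        cell[cell[treatment_col] == 1][duration_col],
                        cell[cell[treatment_col] == 1][event_col],
                        cell[cell[treatment_col] == 0][duration_col],
                        cell[cell[treatment_col] == 0][event_col],
                    )
            else:
                p_lr = np.nan
            rows.append(
                {
                    "stage_variable": stage_variable,
                    "stage_level": level,
                    "rs_group": rs,
                    "n_ct": n_ct,
                    "n_no_ct": n_noct,
                    "hr_ct_vs_noct": hr,
                    "hr_lower95": lo,
                    "hr_upper95": hi,
                    "logrank_p": p_lr,
                    "interaction_p": p_int,
                    "note": "; ".join(x for x in (flag, hr_note, int_note) if x),
                }
            )
    out = pd.DataFrame(rows)
    # rows partition each stratum exactly
    for level in out["stage_level"].unique():
        sub = out[out["stage_level"] == level]
        stratum = (
            work
            if stage_variable == "all"
            else work[work[stage_variable].astype(str) == level]
        )
        in_groups = stratum[signature_group_col].isin(["high", "low"]).sum()
        assert sub["n_ct"].sum() + sub["n_no_ct"].sum() == in_groups
    return out
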