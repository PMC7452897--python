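"""End-to-end desk-scale study orchestration.

Stages: simulate -> extract (+ reproducibility screen) -> fit ->
score -> evaluate -> interaction -> report.  Every stage writes its
artifacts under the output directory and is skipped when its outputs
already exist (delete a stage's files to recompute it); outputs are
deterministic given the config, so a rerun after deleting a cache
reproduces identical downstream numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog
from .features import compute_feature_icc, extract_patient
from .interaction import subgroup_efficacy_table
from .io import (
    adc_from_dwi,
    load_mask,
    load_volume,
    read_feature_table,
    write_feature_table,
    znormalize,
)
from .nomogram import (
    build_nomogram,
    calibration_curve,
    compute_idi,
    compute_nri,
    decision_curve,
    predict_dmfs,
)
from .signature import SignatureModel, build_signature, score, stratify
from .survival import fit_cox, harrell_cindex, logrank_test, time_dependent_auc
from .synthetic import COVARIATE_CODES, PhantomSpec, TrueCohortModel, generate_cohort, perturb_mask

log = logging.getLogger("radsurv")

__all__ = ["PipelineConfig", "run", "report"]

STAGES = ("simulate", "extract", "fit", "score", "evaluate", "interaction")


@dataclass
class PipelineConfig:
    """All knobs of a study run; round-trips losslessly through JSON."""

    outdir: str = "radsurv_run"
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    cohort: dict = field(default_factory=dict)  # TrueCohortModel overrides
    catalog: dict = field(default_factory=dict)  # FeatureCatalog overrides
    clinical_covariates: list[str] = field(
        default_factory=lambda: ["pN", "pT", "cea", "clinical_stage", "location"]
    )
    selection_fraction: float = 0.20
    selection_alpha: float = 0.1
    corr_cutoff: float = 0.6
    n_folds: int = 10
    coarse_mode: str = "intersection"
    icc_enabled: bool = True
    icc_threshold: float = 0.6
    icc_n_patients: int = 30
    icc_magnitude: float = 1.0
    horizons: tuple[float, ...] = (12.0, 24.0, 36.0)
    dca_thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def spec(self) -> PhantomSpec:
        return PhantomSpec(**{**self.phantom, "seed": self.seed})

    def model(self) -> TrueCohortModel:
        return TrueCohortModel(**{**self.cohort, "seed": self.seed})

    def feature_catalog(self) -> FeatureCatalog:
        return FeatureCatalog(**self.catalog)


def _encode_clinical(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    out = df.copy()
    for c in covariates:
        codes = COVARIATE_CODES.get(c)
        if codes is not None and out[c].dtype == object:
            out[c] = out[c].astype(str).map(codes).astype(float)
        else:
            out[c] = pd.to_numeric(out[c])
    return out


def _stage_simulate(cfg: PipelineConfig, outdir: Path, force: bool) -> pd.DataFrame:
    table_path = outdir / "data" / "survival.csv"
    if table_path.exists() and not force:
        log.info("simulate: cached")
        return pd.read_csv(table_path, float_precision="round_trip")
    log.info("simulate: generating cohorts %s", cfg.model().n_patients)
    return generate_cohort(cfg.model(), cfg.spec(), outdir / "data", write_images=True)


def _extract_one(
    data_dir: Path, files: dict[str, str], catalog: FeatureCatalog, mask=None
) -> dict[str, float]:
    t2w = load_volume(data_dir / files["t2w"], "T2W")
    b0 = load_volume(data_dir / files["dwi_b0"], "DWI_b0")
    b1000 = load_volume(data_dir / files["dwi_b1000"], "DWI_b1000")
    mask = mask if mask is not None else load_mask(data_dir / files["mask"])
    adc = adc_from_dwi(b0, b1000)
    import warnings

    with warnings.catch_warnings():
        # homogeneous (zero-amplitude) tumors legitimately produce
        # constant-ROI sub-bands; the per-feature conventions handle them
        warnings.simplefilter("ignore", UserWarning)
        return extract_patient(znormalize(t2w), znormalize(adc), mask, mask, catalog)


def _stage_extract(cfg: PipelineConfig, outdir: Path, force: bool) -> pd.DataFrame:
    feat_path = outdir / "features.csv"
    data_dir = outdir / "data"
    manifest = json.loads((data_dir / "manifest.json").read_text())
    catalog = cfg.feature_catalog()
    if not (feat_path.exists() and not force):
        log.info("extract: %d patients", len(manifest["patients"]))
        rows = {}
        for pid, info in manifest["patients"].items():
            rows[pid] = _extract_one(data_dir, info["files"], catalog)
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.index.name = "patient_id"
        write_feature_table(table, feat_path)
    table = read_feature_table(feat_path)

    retained_path = outdir / "icc_retained.json"
    if cfg.icc_enabled and not (retained_path.exists() and not force):
        primary_ids = [
            pid for pid, info in manifest["patients"].items() if info["cohort"] == "primary"
        ][: cfg.icc_n_patients]
        log.info("extract: reproducibility screen on %d patients", len(primary_ids))
        rows_b = {}
        for i, pid in enumerate(primary_ids):
            files = manifest["patients"][pid]["files"]
            mask = load_mask(data_dir / files["mask"])
            mask_b = perturb_mask(mask, cfg.icc_magnitude, seed=cfg.seed + 7919 + i)
            rows_b[pid] = _extract_one(data_dir, files, catalog, mask=mask_b)
        table_b = pd.DataFrame.from_dict(rows_b, orient="index")
        table_b.index.name = "patient_id"
        icc, retained = compute_feature_icc(
            table.loc[primary_ids], table_b, threshold=cfg.icc_threshold
        )
        retained_path.write_text(json.dumps({"retained": retained}, indent=1))
        icc.to_csv(outdir / "icc.csv")
    return table


def _retained_features(cfg: PipelineConfig, outdir: Path, table: pd.DataFrame) -> list[str]:
    retained_path = outdir / "icc_retained.json"
    if cfg.icc_enabled and retained_path.exists():
        return json.loads(retained_path.read_text())["retained"]
    return list(table.columns)


def _stage_fit(
    cfg: PipelineConfig, outdir: Path, table: pd.DataFrame, surv: pd.DataFrame, force: bool
) -> SignatureModel:
    model_path = outdir / "signature.json"
    if model_path.exists() and not force:
        log.info("fit: cached")
        return SignatureModel.from_json(model_path)
    retained = _retained_features(cfg, outdir, table)
    primary = surv[surv["cohort"] == "primary"].set_index("patient_id")
    feats = table.loc[primary.index, retained]
    # drop features that are constant within the primary cohort
    feats = feats.loc[:, feats.std(ddof=0) > 0]
    log.info("fit: %d patients x %d features", *feats.shape)
    model, screening = build_signature(
        feats,
        primary,
        fraction=cfg.selection_fraction,
        alpha=cfg.selection_alpha,
        corr_cutoff=cfg.corr_cutoff,
        n_folds=cfg.n_folds,
        seed=cfg.seed,
        coarse_mode=cfg.coarse_mode,
    )
    model.to_json(model_path)
    (outdir / "screening.json").write_text(
        json.dumps(
            {
                "n_all": int(len(screening.screen)),
                "coarse": screening.coarse_set,
                "pruned": screening.pruned_set,
                "selected": screening.selected,
            },
            indent=1,
        )
    )
    return model


def _stage_score(
    cfg: PipelineConfig,
    outdir: Path,
    model: SignatureModel,
    table: pd.DataFrame,
    surv: pd.DataFrame,
    force: bool,
) -> pd.DataFrame:
    path = outdir / "scores.csv"
    if path.exists() and not force:
        return pd.read_csv(path, float_precision="round_trip")
    scores = score(model, table)
    out = surv.copy()
    out["radiomic_signature"] = scores.loc[out["patient_id"]].to_numpy()
    out["risk_group"] = stratify(model, pd.Series(
        out["radiomic_signature"].to_numpy(), index=out["patient_id"]
    )).to_numpy()
    out.to_csv(path, index=False)
    return out


def _cohort_metrics(cfg: PipelineConfig, sub: pd.DataFrame) -> dict:
    hi = sub[sub["risk_group"] == "high"]
    lo = sub[sub["risk_group"] == "low"]
    out: dict = {"n": int(len(sub)), "n_high": int(len(hi)), "n_low": int(len(lo))}
    if len(hi) and len(lo):
        stat, p = logrank_test(
            hi["time_months"], hi["event"], lo["time_months"], lo["event"]
        )
        out["logrank_p"] = p
        work = sub[["time_months", "event"]].copy()
        work["high"] = (sub["risk_group"] == "high").astype(float)
        try:
            fit = fit_cox(work, covariates=["high"])
            out["hr_high_vs_low"] = float(fit.hazard_ratios["high"])
            out["hr_ci"] = [float(fit.ci_lower["high"]), float(fit.ci_upper["high"])]
        except (RuntimeError, ValueError) as err:
            out["hr_high_vs_low"] = None
            out["hr_note"] = str(err)
    c, ci = harrell_cindex(
        sub["radiomic_signature"], sub["time_months"], sub["event"]
    )
    out["cindex_signature"] = c
    out["cindex_signature_ci"] = list(ci)
    try:
        aucs = time_dependent_auc(
            sub["radiomic_signature"], sub["time_months"], sub["event"], cfg.horizons
        )
        out["auc"] = {str(int(h)): float(a) for h, a in aucs.items()}
    except ValueError as err:
        out["auc_note"] = str(err)
    return out


def _stage_evaluate(
    cfg: PipelineConfig, outdir: Path, scored: pd.DataFrame, force: bool
) -> dict:
    path = outdir / "evaluation.json"
    if path.exists() and not force:
        return json.loads(path.read_text())
    results: dict = {"cohorts": {}, "models": {}}
    for cohort in scored["cohort"].unique():
        results["cohorts"][cohort] = _cohort_metrics(
            cfg, scored[scored["cohort"] == cohort]
        )

    coded = _encode_clinical(scored, cfg.clinical_covariates)
    primary = coded[coded["cohort"] == "primary"]
    clin_nom = build_nomogram(
        primary, cfg.clinical_covariates, horizons=cfg.horizons
    )
    rad_covs = cfg.clinical_covariates + ["radiomic_signature"]
    rad_nom = build_nomogram(primary, rad_covs, horizons=cfg.horizons)
    h = float(max(cfg.horizons))
    for cohort in coded["cohort"].unique():
        sub = coded[coded["cohort"] == cohort]
        grid = {}
        for name, nom, covs in (
            ("clinical_nomogram", clin_nom, cfg.clinical_covariates),
            ("radiomic_nomogram", rad_nom, rad_covs),
        ):
            lp = sub[covs].to_numpy(dtype=float) @ np.array(
                [nom.cox.coefficients[c] for c in covs]
            )
            c, ci = harrell_cindex(lp, sub["time_months"], sub["event"])
            grid[name] = {"cindex": c, "ci": list(ci)}
        grid["radiomic_signature"] = {
            "cindex": results["cohorts"][cohort]["cindex_signature"],
            "ci": results["cohorts"][cohort]["cindex_signature_ci"],
        }
        results["models"][cohort] = grid

        pred_new = 1.0 - predict_dmfs(rad_nom, sub, h)
        pred_old = 1.0 - predict_dmfs(clin_nom, sub, h)
        nri = compute_nri(pred_old, pred_new, sub["time_months"], sub["event"], h)
        idi = compute_idi(pred_old, pred_new, sub["time_months"], sub["event"], h)
        results["models"][cohort]["nri_radiomic_vs_clinical"] = nri["nri"]
        results["models"][cohort]["idi_radiomic_vs_clinical"] = idi["idi"]

        cal = calibration_curve(
            pd.Series(predict_dmfs(rad_nom, sub, h)), sub["time_months"],
            sub["event"], h,
        )
        cal.to_csv(outdir / f"calibration_{cohort}.csv")
        dca = decision_curve(
            pred_new, sub["time_months"], sub["event"], h,
            np.asarray(cfg.dca_thresholds),
        )
        dca.to_csv(outdir / f"dca_{cohort}.csv", index=False)
    path.write_text(json.dumps(results, indent=1))
    return results


def _stage_interaction(
    cfg: PipelineConfig, outdir: Path, scored: pd.DataFrame, force: bool
) -> pd.DataFrame:
    path = outdir / "interaction.csv"
    if path.exists() and not force:
        return pd.read_csv(path)
    work = scored.copy()
    work["adjuvant_ct"] = _encode_clinical(work, ["adjuvant_ct"])["adjuvant_ct"]
    tables = [
        subgroup_efficacy_table(work, stage_variable=sv) for sv in ("all", "pT", "pN")
    ]
    out = pd.concat(tables, ignore_index=True)
    out.to_csv(path, index=False)
    return out


def run(cfg: PipelineConfig, force: bool = False, stages: list[str] | None = None) -> Path:
    """Execute the study end to end; returns the artifacts directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_json(outdir / "config.json")
    stages = stages or list(STAGES)
    try:
        surv = _stage_simulate(cfg, outdir, force and "simulate" in stages)
        if "extract" not in stages:
            return outdir
        table = _stage_extract(cfg, outdir, force and "extract" in stages)
        if "fit" not in stages:
            return outdir
        model = _stage_fit(cfg, outdir, table, surv, force and "fit" in stages)
        if "score" not in stages:
            return outdir
        scored = _stage_score(cfg, outdir, model, table, surv, force and "score" in stages)
        if "evaluate" in stages:
            _stage_evaluate(cfg, outdir, scored, force and "evaluate" in stages)
        if "interaction" in stages:
            _stage_interaction(cfg, outdir, scored, force and "interaction" in stages)
    except Exception as err:
        raise RuntimeError(f"pipeline stage failed: {err}") from err
    return outdir


def report(outdir: str | Path, figures: bool = True) -> str:
    """Human-readable study summary assembled from the artifact files."""
    outdir = Path(outdir)
    missing = [
        f for f in ("evaluation.json", "scores.csv", "interaction.csv")
        if not (outdir / f).exists()
    ]
    lines = ["# Radiomic signature study report", ""]
    if missing:
        lines.append(f"INCOMPLETE RUN - missing artifacts: {missing}")
        (outdir / "report.txt").write_text("\n".join(lines))
        return "\n".join(lines)
    results = json.loads((outdir / "evaluation.json").read_text())
    scored = pd.read_csv(outdir / "scores.csv")
    inter = pd.read_csv(outdir / "interaction.csv")

    lines.append("## Risk stratification (high vs low signature)")
    for cohort, m in results["cohorts"].items():
        hr = m.get("hr_high_vs_low")
        hr_s = f"{hr:.2f}" if hr else "NA"
        auc = m.get("auc", {})
        auc_s = ", ".join(f"{k}m: {v:.3f}" for k, v in auc.items())
        lines.append(
            f"- {cohort} (n={m['n']}, high={m['n_high']}/low={m['n_low']}): "
            f"log-rank p={m.get('logrank_p', float('nan')):.2e}, HR={hr_s}, "
            f"C-index={m['cindex_signature']:.3f}, AUC[{auc_s}]"
        )
    lines.append("")
    lines.append("## C-index grid (signature / clinical nomogram / radiomic nomogram)")
    for cohort, grid in results["models"].items():
        lines.append(
            f"- {cohort}: signature={grid['radiomic_signature']['cindex']:.3f}, "
            f"clinical={grid['clinical_nomogram']['cindex']:.3f}, "
            f"radiomic={grid['radiomic_nomogram']['cindex']:.3f}, "
            f"NRI={grid['nri_radiomic_vs_clinical']:.3f}, "
            f"IDI={grid['idi_radiomic_vs_clinical']:.3f}"
        )
    lines.append("")
    lines.append("## Chemotherapy interaction (pooled cohorts)")
    for _, row in inter.iterrows():
        hr = row["hr_ct_vs_noct"]
        hr_s = f"{hr:.2f} ({row['hr_lower95']:.2f}-{row['hr_upper95']:.2f})" if np.isfinite(hr) else "NA"
        lines.append(
            f"- {row['stage_variable']}={row['stage_level']} & {row['rs_group']} RS: "
            f"CT {row['n_ct']} vs no-CT {row['n_no_ct']}, HR={hr_s}, "
            f"log-rank p={row['logrank_p']:.3f}, interaction p={row['interaction_p']:.2e}"
        )
    text = "\n".join(lines)
    (outdir / "report.txt").write_text(text)
    if figures:
        _figures(outdir, scored)
    return text


def _figures(outdir: Path, scored: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .survival import km_estimate

    cohorts = list(scored["cohort"].unique())
    fig, axes = plt.subplots(1, len(cohorts), figsize=(4 * len(cohorts), 3.2))
    axes = np.atleast_1d(axes)
    for ax, cohort in zip(axes, cohorts):
        sub = scored[scored["cohort"] == cohort]
        for grp, color in (("high", "tab:red"), ("low", "tab:blue")):
            g = sub[sub["risk_group"] == grp]
            if not len(g):
                continue
            km = km_estimate(g["time_months"], g["event"])
            ax.step(km.times, km.survival, where="post", color=color, label=f"{grp} RS")
        ax.set_title(cohort)
        ax.set_xlabel("months")
        ax.set_ylabel("DMFS")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "km_curves.png", dpi=120)
    plt.close(fig)
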