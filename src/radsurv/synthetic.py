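"""Synthetic multi-cohort study generator.

The real study data (rectal-MRI volumes + follow-up records from five
hospitals) are private, so every downstream stage is exercised on
synthetic studies with known ground truth:

* **Phantoms** — ellipsoidal tumors on a 3D grid carrying a stationary
  correlated Gaussian texture whose amplitude grows linearly with a
  per-patient latent risk, in both the T2W-like channel and the true
  ADC field; DWI channels are generated to satisfy the monoexponential
  decay S(b) = S(0) exp(-b ADC) exactly, so heterogeneity is
  monotonically linked to hazard through the images.
* **Clinical covariates** — i.i.d. categorical draws with per-cohort
  marginals defaulting to the published multicenter cohort tables
  (four cohorts of 176/154/150/149 patients).
* **Outcomes** — proportional-hazards DMFS times with an exponential
  baseline, exponential + administrative censoring, and a built-in
  chemotherapy-by-risk-group interaction: treatment is protective in
  the low-latent-risk half and harmful in the high half, mirroring the
  qualitative treatment-interaction pattern the pipeline must detect.

Every generator is a pure function of (spec/model, seed).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ROIMask, VolumetricImage, save_mask, save_volume

__all__ = [
    "PhantomSpec",
    "TrueCohortModel",
    "PUBLISHED_COHORT_MARGINALS",
    "COVARIATE_CODES",
    "generate_phantom_pair",
    "simulate_survival",
    "simulate_clinical",
    "perturb_mask",
    "generate_cohort",
]

COHORTS = ("primary", "v1", "v2", "v3")

#: integer coding of categorical covariates used in linear predictors
COVARIATE_CODES: dict[str, dict[str, int]] = {
    "clinical_stage": {"II": 0, "III": 1},
    "location": {">10": 0, "5-10": 1, "<5": 2},
    "cea": {"<5": 0, ">=5": 1},
    "neoadjuvant": {"0": 0, "1": 1},
    "adjuvant_ct": {"0": 0, "1": 1},
    "pN": {"0": 0, "1": 1, "2": 2},
    "pT": {"0": 0, "1/2": 1, "3/4": 2},
}

#: per-cohort categorical marginals emulating the published
#: demographic/clinicopathological tables of the four cohorts
PUBLISHED_COHORT_MARGINALS: dict[str, dict[str, dict[str, float]]] = {
    "primary": {
        "clinical_stage": {"II": 0.494, "III": 0.506},
        "location": {">10": 0.176, "5-10": 0.369, "<5": 0.455},
        "cea": {"<5": 0.619, ">=5": 0.381},
        "neoadjuvant": {"0": 0.642, "1": 0.358},
        "adjuvant_ct": {"0": 0.335, "1": 0.665},
        "pN": {"0": 0.455, "1": 0.375, "2": 0.170},
        "pT": {"0": 0.023, "1/2": 0.136, "3/4": 0.841},
    },
    "v1": {
        "clinical_stage": {"II": 0.149, "III": 0.851},
        "location": {">10": 0.669, "5-10": 0.325, "<5": 0.006},
        "cea": {"<5": 0.526, ">=5": 0.474},
        "neoadjuvant": {"0": 0.0, "1": 1.0},
        "adjuvant_ct": {"0": 0.669, "1": 0.331},
        "pN": {"0": 0.597, "1": 0.279, "2": 0.124},
        "pT": {"0": 0.227, "1/2": 0.195, "3/4": 0.578},
    },
    "v2": {
        "clinical_stage": {"II": 0.280, "III": 0.720},
        "location": {">10": 0.073, "5-10": 0.540, "<5": 0.387},
        "cea": {"<5": 0.760, ">=5": 0.240},
        "neoadjuvant": {"0": 0.460, "1": 0.540},
        "adjuvant_ct": {"0": 0.180, "1": 0.820},
        "pN": {"0": 0.573, "1": 0.273, "2": 0.154},
        "pT": {"0": 0.180, "1/2": 0.173, "3/4": 0.647},
    },
    "v3": {
        "clinical_stage": {"II": 0.356, "III": 0.644},
        "location": {">10": 0.081, "5-10": 0.624, "<5": 0.295},
        "cea": {"<5": 0.658, ">=5": 0.342},
        "neoadjuvant": {"0": 0.423, "1": 0.577},
        "adjuvant_ct": {"0": 0.228, "1": 0.772},
        "pN": {"0": 0.678, "1": 0.161, "2": 0.161},
        "pT": {"0": 0.0, "1/2": 0.174, "3/4": 0.826},
    },
}


@dataclass
class PhantomSpec:
    """Geometry and texture parameters of the tumor phantoms."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_range_mm: tuple[float, float] = (5.0, 9.0)
    #: texture-noise amplitude = intercept + slope * latent_risk (clipped >= 0)
    heterogeneity_link: tuple[float, float] = (0.25, 0.20)
    texture_correlation_length_mm: float = 1.5
    background_t2w: float = 1.0
    tumor_contrast_t2w: float = 2.0
    background_adc: float = 1.6  # 1e-3 mm^2/s, normal tissue
    tumor_contrast_adc: float = -0.6  # tumors are diffusion-restricted
    s_b0: float = 1000.0  # DWI b=0 signal scale
    acquisition_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tumor_radius_range_mm
        if not 0 < lo <= hi:
            raise ValueError("tumor radius range must satisfy 0 < lo <= hi")
        if self.heterogeneity_link[1] < 0:
            raise ValueError("heterogeneity slope must be >= 0")
        if self.texture_correlation_length_mm <= 0:
            raise ValueError("texture correlation length must be positive")
        if any(n <= 0 for n in self.grid_shape) or any(
            s <= 0 for s in self.spacing_mm
        ):
            raise ValueError("grid shape and spacing must be positive")
        half_extent = [n * s / 2 for n, s in zip(self.grid_shape, self.spacing_mm)]
        if hi >= min(half_extent):
            raise ValueError(
                f"maximum tumor radius {hi} mm does not fit the grid "
                f"(half extents {half_extent} mm)"
            )


@dataclass
class TrueCohortModel:
    """Ground-truth hazard model of the synthetic study.

    The linear predictor of patient i is

        lp_i = beta_risk * z_i + sum_c beta_clinical[c] * code(x_ic)
               + beta_treatment * tx_i + beta_interaction * tx_i * 1[z_i > med(z)]

    with latent risk z ~ N(0, 1) and med(z) the pooled study median.
    Event times are exponential with rate baseline_rate * exp(lp);
    censoring is the earlier of an exponential censoring time and an
    administrative cutoff.
    """

    n_patients: dict[str, int] = field(
        default_factory=lambda: {"primary": 176, "v1": 154, "v2": 150, "v3": 149}
    )
    beta_risk: float = 1.0
    beta_clinical: dict[str, float] = field(
        default_factory=lambda: {"pN": 0.35, "cea": 0.25}
    )
    beta_treatment: float = -0.29  # protective in the low-risk half
    beta_interaction: float = 0.82  # flips to harmful in the high-risk half
    baseline_rate: float = 0.012  # events/month
    censor_rate: float = 0.004  # events/month
    admin_censor_months: float = 60.0
    covariate_marginals: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {
            c: {k: dict(v) for k, v in PUBLISHED_COHORT_MARGINALS[c].items()} for c in COHORTS
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.censor_rate < 0 or self.admin_censor_months <= 0:
            raise ValueError("censoring parameters must be positive")
        if any(n <= 0 for n in self.n_patients.values()):
            raise ValueError("cohort sizes must be positive")
        for cohort, margs in self.covariate_marginals.items():
            for cov, freqs in margs.items():
                total = sum(freqs.values())
                if abs(total - 1.0) > 0.005:
                    raise ValueError(
                        f"{cohort}/{cov}: frequencies sum to {total:.3f}, not 1"
                    )
                # absorb rounding of published percentages
                self.covariate_marginals[cohort][cov] = {
                    k: v / total for k, v in freqs.items()
                }


def _correlated_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    corr_length_mm: float,
) -> np.ndarray:
    """Unit-variance stationary Gaussian random field (smoothed white noise)."""
    white = rng.standard_normal(shape)
    sigma = [corr_length_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma, mode="wrap")
    return smooth / smooth.std()


def _ellipsoid_mask(
    rng: np.random.Generator, spec: PhantomSpec
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = spec.tumor_radius_range_mm
    radii = rng.uniform(lo, hi, size=3)
    center = (np.asarray(spec.grid_shape) - 1) / 2.0
    grids = np.indices(spec.grid_shape).astype(float)
    r2 = np.zeros(spec.grid_shape)
    for axis in range(3):
        r2 += ((grids[axis] - center[axis]) * spec.spacing_mm[axis] / radii[axis]) ** 2
    return r2 <= 1.0, radii


def generate_phantom_pair(
    spec: PhantomSpec, latent_risk: float, seed: int
) -> tuple[VolumetricImage, VolumetricImage, VolumetricImage, ROIMask]:
    """One patient's (T2W, DWI b=0, DWI b=1000, mask) phantom set.

    The tumor is an ellipsoid with axes drawn from the spec's radius
    range; inside it both channels carry a correlated texture with
    amplitude ``intercept + slope * latent_risk``.  The two DWI
    channels satisfy S_b1000 = S_b0 exp(-1000 * ADC_true) voxelwise.
    Deterministic given (spec, latent_risk, seed).
    """
    if not np.isfinite(latent_risk):
        raise ValueError("latent_risk must be finite")
    rng = np.random.default_rng(seed)
    inside, _ = _ellipsoid_mask(rng, spec)
    if not inside.any():
        raise ValueError("tumor does not cover any voxel on this grid")
    amp = max(0.0, spec.heterogeneity_link[0] + spec.heterogeneity_link[1] * latent_risk)
    tex_t2w = _correlated_field(
        rng, spec.grid_shape, spec.spacing_mm, spec.texture_correlation_length_mm
    )
    tex_adc = _correlated_field(
        rng, spec.grid_shape, spec.spacing_mm, spec.texture_correlation_length_mm
    )
    noise = rng.standard_normal(spec.grid_shape) * spec.acquisition_noise_sd

    t2w = spec.background_t2w + spec.tumor_contrast_t2w * inside + noise
    t2w = t2w + amp * tex_t2w * inside

    adc_true = spec.background_adc + spec.tumor_contrast_adc * inside
    adc_true = adc_true + 0.3 * amp * tex_adc * inside
    adc_true = np.clip(adc_true, 0.05, None)  # physical ADC stays positive

    b0_vox = np.full(spec.grid_shape, spec.s_b0, dtype=float)
    # ADC in 1e-3 mm^2/s and b = 1000 s/mm^2 => exponent is just -adc_true
    b1000_vox = b0_vox * np.exp(-adc_true)

    sp = spec.spacing_mm
    return (
        VolumetricImage(t2w, sp, "T2W"),
        VolumetricImage(b0_vox, sp, "DWI_b0"),
        VolumetricImage(b1000_vox, sp, "DWI_b1000"),
        ROIMask(inside, sp),
    )


def simulate_survival(
    linear_predictors: np.ndarray, model: TrueCohortModel, seed: int
) -> pd.DataFrame:
    """Proportional-hazards event times with censoring.

    Returns columns ``time_months`` and ``event`` for the given linear
    predictors.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictors")
    rng = np.random.default_rng(seed)
    n = lp.size
    t_event = rng.exponential(1.0 / (model.baseline_rate * np.exp(lp)))
    if model.censor_rate > 0:
        t_cens = rng.exponential(1.0 / model.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, model.admin_censor_months)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time_months": time, "event": event})


def simulate_clinical(
    model: TrueCohortModel, cohort: str, n: int, seed: int
) -> pd.DataFrame:
    """i.i.d. categorical covariate draws from the cohort's marginals."""
    if cohort not in model.covariate_marginals:
        raise ValueError(
            f"unknown cohort {cohort!r}; known: {sorted(model.covariate_marginals)}"
        )
    rng = np.random.default_rng(seed)
    cols = {}
    for cov, freqs in model.covariate_marginals[cohort].items():
        levels = list(freqs)
        probs = np.array([freqs[k] for k in levels])
        cols[cov] = rng.choice(levels, size=n, p=probs)
    df = pd.DataFrame(cols)
    df["cohort"] = cohort
    return df


def perturb_mask(mask: ROIMask, magnitude: float, seed: int) -> ROIMask:
    """Random boundary dilation/erosion emulating a second observer.

    The boundary moves by at most ``magnitude`` voxels (driven by a
    smooth random field), so the interior core deeper than
    ``magnitude`` is always preserved.  ``magnitude`` must be smaller
    than the tumor's inscribed radius.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    if magnitude == 0:
        return ROIMask(mask.voxels.copy(), mask.spacing_mm)
    inradius = ndimage.distance_transform_edt(mask.voxels).max()
    if magnitude >= inradius:
        raise ValueError(
            f"magnitude {magnitude} >= inscribed tumor radius {inradius:.1f} voxels"
        )
    # signed voxel distance to the boundary: negative inside
    d_out = ndimage.distance_transform_edt(~mask.voxels)
    d_in = ndimage.distance_transform_edt(mask.voxels)
    signed = d_out - d_in
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal(mask.shape), 2.0, mode="wrap")
    field = field / np.abs(field).max()  # in [-1, 1]
    new = signed <= magnitude * field
    out = ROIMask(new, mask.spacing_mm)
    assert out.n_voxels > 0
    return out


def _encode(clinical: pd.DataFrame) -> pd.DataFrame:
    """Map categorical levels to integer codes for linear predictors."""
    coded = {}
    for cov, codes in COVARIATE_CODES.items():
        if cov in clinical:
            coded[cov] = clinical[cov].astype(str).map(codes).astype(float)
    return pd.DataFrame(coded, index=clinical.index)


def generate_cohort(
    model: TrueCohortModel,
    spec: PhantomSpec,
    outdir: str | Path,
    write_images: bool = True,
) -> pd.DataFrame:
    """Generate the full multi-cohort study on disk.

    Writes one directory per cohort with NIfTI phantom volumes + masks
    (optional), a pooled ``survival.csv`` and a ``manifest.json``
    recording the ground-truth parameters and per-patient latent risks
    so recovery can be scored without private state.  Returns the
    pooled survival/covariate table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(model.seed)
    records = []
    for cohort in model.n_patients:
        n = model.n_patients[cohort]
        clin = simulate_clinical(
            model, cohort, n, seed=int(master.integers(2**31))
        )
        clin["latent_risk"] = np.random.default_rng(
            int(master.integers(2**31))
        ).standard_normal(n)
        clin["patient_id"] = [f"{cohort}_{i:04d}" for i in range(n)]
        records.append(clin)
    table = pd.concat(records, ignore_index=True)

    med = float(np.median(table["latent_risk"]))
    coded = _encode(table)
    lp = model.beta_risk * table["latent_risk"].to_numpy()
    for cov, beta in model.beta_clinical.items():
        lp = lp + beta * coded[cov].to_numpy()
    tx = coded["adjuvant_ct"].to_numpy()
    high = (table["latent_risk"].to_numpy() > med).astype(float)
    lp = lp + model.beta_treatment * tx + model.beta_interaction * tx * high
    surv = simulate_survival(lp, model, seed=int(master.integers(2**31)))
    table = pd.concat([table, surv], axis=1)
    table["true_high_risk"] = high.astype(int)

    image_files: dict[str, dict[str, str]] = {}
    for cohort in model.n_patients:
        cdir = outdir / cohort
        cdir.mkdir(exist_ok=True)
        sub = table[table["cohort"] == cohort]
        if write_images:
            for _, row in sub.iterrows():
                pid = row["patient_id"]
                pseed = int(
                    np.random.default_rng(
                        [model.seed, zlib.crc32(pid.encode())]
                    ).integers(2**31)
                )
                t2w, b0, b1000, mask = generate_phantom_pair(
                    spec, float(row["latent_risk"]), pseed
                )
                files = {
                    "t2w": f"{pid}_t2w.nii.gz",
                    "dwi_b0": f"{pid}_dwib0.nii.gz",
                    "dwi_b1000": f"{pid}_dwib1000.nii.gz",
                    "mask": f"{pid}_mask.nii.gz",
                }
                save_volume(t2w, cdir / files["t2w"])
                save_volume(b0, cdir / files["dwi_b0"])
                save_volume(b1000, cdir / files["dwi_b1000"])
                save_mask(mask, cdir / files["mask"])
                image_files[pid] = {k: f"{cohort}/{v}" for k, v in files.items()}

    table.to_csv(outdir / "survival.csv", index=False)
    manifest = {
        "model": _jsonable(dataclasses.asdict(model)),
        "spec": _jsonable(dataclasses.asdict(spec)),
        "latent_risk_median": med,
        "n_total": int(len(table)),
        "write_images": bool(write_images),
        "patients": {
            row["patient_id"]: {
                "latent_risk": float(row["latent_risk"]),
                "cohort": row["cohort"],
                "files": image_files.get(row["patient_id"], {}),
            }
            for _, row in table.iterrows()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return table


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
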