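# Methods

This note documents the models, conventions and numerical choices
behind `radsurv`, and what the synthetic studies do and do not show
about real rectal-MRI data.

## Synthetic study generator

**Phantoms.** Each patient is an ellipsoidal tumor (axes drawn
uniformly from the configured radius range, default 5–9 mm on a 32³
grid of 1 mm voxels) on a flat background. Inside the tumor both
channels carry a stationary correlated Gaussian texture, built by
smoothing white noise with a Gaussian kernel whose width is the
configured correlation length (default 1.5 mm) and rescaling to unit
variance. The texture amplitude is `intercept + slope · z` (defaults
0.25 + 0.20 z, clipped at 0) for a per-patient latent risk z ~ N(0,1):
higher-risk tumors are rougher, which is the only image–outcome link,
standing in for the intra-tumor heterogeneity that radiomic features
quantify in real tumors. The ADC channel is generated as a *true*
diffusion field (background 1.6, tumor 1.0 ×10⁻³ mm²/s — tumors are
diffusion-restricted — plus 0.3× the texture), and the DWI pair is
derived from it exactly via S(b) = S(0)·exp(−b·ADC), so the two-point
monoexponential ADC reconstruction is exact by construction. The T2W
channel additionally carries small i.i.d. acquisition noise (σ = 0.02).

**Covariates and outcomes.** Clinical covariates are i.i.d.
categorical draws whose per-cohort marginals default to the published
four-cohort multicenter tables (cohort sizes 176/154/150/149 = 629).
Survival follows a proportional-hazards model with exponential
baseline (default 0.012 events/month):

    lp = β_risk·z + Σ_c β_c·code(x_c) + β_tx·tx + β_int·tx·1[z > med(z)]

with defaults β_risk = 1, β_pN = 0.35, β_cea = 0.25, β_tx = −0.29 and
β_int = 0.82, i.e. chemotherapy is mildly protective in the
low-latent-risk half (HR ≈ 0.75) and harmful in the high half
(HR ≈ 1.7) — the qualitative treatment-interaction pattern the
analysis must expose. Censoring is the earlier of an exponential
censoring time (0.004/month) and a 60-month administrative cutoff.
The interaction is defined on the pooled latent-risk median split,
mirroring how the fitted signature is dichotomized. No published
hazard scale exists for these cohorts; the defaults were chosen once
for realistic event rates (~30–50 % events by 60 months) and adequate
test power, not epidemiological calibration. A ground-truth manifest
(parameters, per-patient latent risks) is part of the on-disk dataset
so recovery can be scored without private state.

**What the phantoms are not.** No MRI physics (coil bias, distortion,
Rician noise), no inter-scanner effects, no irregular tumor shapes,
and a single global texture–hazard mechanism. Passing tests show the
*pipeline* recovers planted structure; they do not validate the
clinical signature itself.

## Imaging conventions

* Axis order (x, y, z), 0-based; masks must share the exact grid of
  their image — no resampling (synthetic data are generated aligned;
  real-data resampling is out of scope).
* Z-normalization is per patient per sequence over the whole volume.
* Gray-level discretization is equal-width with a fixed bin *count*
  (default 32) over the ROI intensity range; a fixed bin width is
  ill-posed after z-scoring. The ROI maximum maps to the top bin.
* Non-positive DWI signals clamp ADC to 0 with a counted warning
  rather than failing the scan.

## Feature catalog

The exact per-group feature lists of the original in-house toolbox
are not public; the catalog here is an IBSI-consistent reconstruction
constrained to the published group cardinalities — 8 shape, 15
first-order, 53 texture, 544 wavelet (= 8 sub-bands × 68), 620 per
sequence, 1240 per patient — and is config-swappable.

* **Shape (8):** volume, surface area, surface:volume, sphericity
  π^⅓(6V)^⅔/A, compactness₁, compactness₂, spherical disproportion,
  maximum 3D diameter. Surface area uses the exposed-voxel-face
  convention, which makes a cube's area exactly 6a² (hence cube
  sphericity (π/6)^⅓) and keeps single-voxel masks defined. Under
  this convention a digitized ball's staircase surface tends to 1.5×
  the smooth area, so ball sphericity converges to ⅔, not 1 — a known
  property of face counting, tested as such.
* **First-order (15):** mean, median, min, max, range, variance, SD,
  mean absolute deviation, RMS, energy, entropy (Shannon, log₂, on
  the discretized histogram), uniformity, skewness, kurtosis (excess,
  population moments), 90th percentile. Skewness/kurtosis of a
  constant ROI are defined as 0 with a warning, not NaN.
* **Texture (53 = 24 GLCM + 16 GLRLM + 13 GLSZM):** all 3D. GLCM uses
  the 13 unique distance-1 offsets, symmetric pairs, per-direction
  normalized matrices averaged (so results are invariant to offset
  enumeration order); single-gray-level ROIs define correlation as 1.
  GLRLM pools run counts over the same 13 directions; run percentage
  divides by (voxels × directions). GLSZM uses 26-connected zones.
* **Wavelet (544):** single-level 3D *undecimated* transform — the 1D
  low/high-pass decomposition filters of the chosen basis (default
  Haar) applied along each axis by periodic correlation, no
  downsampling — so all 8 sub-bands keep the ROI grid and the mask
  applies unchanged. Haar makes detail sub-bands of a constant volume
  exactly zero. First-order + texture are recomputed per sub-band.
* **Reproducibility screen:** ICC(2,1) — two-way random effects,
  absolute agreement, single measurement — between feature tables
  from original and perturbed masks (a simulated second observer);
  retain ICC > 0.6. Degenerate (no between-subject variance) features
  get ICC 0 with a warning.

## Signature construction

Features are z-scored with *primary-cohort* statistics; validation
cohorts reuse those statistics unchanged — required for a portable
cutoff. The cascade:

1. **Univariate Cox screen** — one single-covariate fit per feature
   (Efron ties), implemented as a vectorized Newton–Raphson across all
   features and verified against lifelines to 1e-5; non-converging or
   constant features record p = 1 with a warning.
2. **Coarse filter** — keep features with p < 0.1 that are also among
   the ⌈20 % of all features⌉ smallest p-values (ties broken by stable
   catalog order). The phrase "top 20 % with p < 0.1" is ambiguous;
   the intersection reading is the default and a
   `within_significant` mode implements the other reading.
3. **Correlation pruning** — greedy: while any pair has |r| > 0.6,
   take the largest-|r| pair (ties: lexicographic names) and drop the
   member with the larger mean absolute correlation against the
   currently retained set (ties: the later catalog name). Constant
   columns correlate as 0 with a warning. The survivors satisfy
   max |r| ≤ 0.6 by construction.
4. **LASSO-Cox** — ℓ1-penalized partial likelihood (coxnet path),
   penalty chosen by seeded 10-fold cross-validated Breslow deviance.
   The default rule is the glmnet-style **one-standard-error** lambda
   (largest penalty within 1 SE of the deviance minimum that retains
   at least one feature): in planted-feature simulations the
   lambda-at-minimum rule admitted 10–30 false positives while the
   1 SE rule kept all planted features with few extras, matching the
   sparsity (4 features from ~1240) such signatures show in practice.
   `lambda_rule="min"` is available. All-zero coefficient sets raise
   an error advising a smaller penalty grid.

The signature score is the penalized linear predictor; the primary
median is the cutoff, ties go to low risk (conservative).

## Survival evaluation

* Cox models use Efron tie handling throughout (lifelines).
* Time-dependent ROC is the cumulative-case / dynamic-control IPCW
  estimator (scikit-survival), horizons 12/24/36 months; it equals
  plain pair counting when censoring is absent.
* Harrell's C counts pairs where the shorter observed time had an
  event (tied event times not comparable; marker ties = ½). The 95 %
  CI uses a leave-one-subject-out jackknife SE — a simple asymptotic
  normal interval chosen over closed-form Noether-type variances
  because it makes no additional tie assumptions; on null data it
  covers 0.5 as expected.
* Baseline comparisons: Shapiro screen at 0.05 routes continuous
  variables to t vs Mann–Whitney; expected cell counts < 5 route 2×2
  tables to Fisher; all tests two-sided.

## Nomograms, decision curves, reclassification

The nomogram maps each covariate to 0–100 points (100 = the largest
|β|·range contribution) with an exact inverse to the linear predictor,
so point-scale predictions equal the Cox model's step-function
survival S(t|x) = S₀(t)^exp(lp) to 1e-9 (S₀ is the Breslow baseline
re-anchored to covariate value zero). Calibration bins predictions by
quintile (degenerate predictions fall back to one group with a
warning) against the group Kaplan–Meier estimate. Decision curves and
the continuous NRI/IDI handle censoring by Kaplan–Meier weighting at
the horizon: subjects censored before it contribute fractionally with
P(event by t | alive at censoring) = 1 − S(t)/S(c); with no censoring
everything reduces to 2×2 counting, which the tests verify against
brute-force oracles. The default NRI/IDI horizon is 36 months, the
furthest evaluated year.

## Treatment-interaction analysis

Interaction p-values come from the Wald test of the product term in a
Cox model with both main effects (factors coded numerically; ordinal
for staged variables). Subgroup hazard ratios are within-cell Cox
fits of treatment alone, matching the per-cell framing of published
efficacy tables; cells with an empty arm or no events in an arm
report an undefined HR with the reason, and arms with fewer than two
subjects are flagged but never dropped, so the rows always partition
the stratum.

## Pipeline and problem sizes

The orchestrated study (simulate → extract → ICC screen → fit →
score → evaluate → interaction → report) caches each stage on disk
and is byte-reproducible given the config (cached tables are re-read
with round-trip float parsing for exactly this reason). The
reproducibility screen uses the first 30 primary-cohort patients with
magnitude-1 mask perturbation — a deliberate subset, as inter-observer
studies typically re-read a sample rather than the full cohort. The
bundled acceptance run uses the published cohort sizes
(176/154/150/149) on 32³ phantom grids, which keeps a full study in
the minutes range on one CPU; unit tests use smaller grids and
cohorts. Monte-Carlo checks (type-I error, planted-feature recovery,
null discrimination) use 1000–2000 replicates or 20 seeded runs as
noted in the tests.

## Known limitations

* The feature catalog is a cardinality-faithful reconstruction, not
  the original toolbox's exact formulas; which features a fitted
  signature selects is data-dependent and is not a test target.
* External published clinical nomograms can be compared only through
  a user-supplied scoring function; no coefficients are bundled.
* No competing risks, frailty, proportional-hazards diagnostics,
  bootstrap CIs for NRI/IDI, DICOM ingestion, or 2D feature variants.
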