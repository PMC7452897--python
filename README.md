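# radsurv

Multiparametric MRI radiomics signatures for distant-metastasis-free
survival (DMFS) in locally advanced rectal cancer (LARC) — as a tested,
reusable Python pipeline.

## The problem

Distant metastasis is the main cause of treatment failure in LARC, and
adjuvant chemotherapy helps only some patients. A *radiomic signature*
— a sparse linear combination of quantitative image features extracted
from routine rectal MRI (T2-weighted imaging plus an apparent diffusion
coefficient map) — can stratify postoperative metastasis risk and flag
which patient subgroups stand to benefit, or be harmed, by adjuvant
chemotherapy. Patient MRI studies of this kind are private, so this
package ships a first-class synthetic study generator: tumor phantoms
whose intensity heterogeneity is monotonically linked to a latent
hazard, clinical covariates with realistic multicenter marginals, and
censored proportional-hazards outcomes with a planted
chemotherapy-by-risk interaction. Every stage of the analysis is
therefore testable end to end with known ground truth.

## What it computes

* **Feature extraction** — per MR sequence: 8 shape, 15 first-order,
  53 texture (24 GLCM + 16 GLRLM + 13 GLSZM, all 3D) and
  8 × (15 + 53) = 544 undecimated-wavelet sub-band features: 620 per
  sequence, **1240 per patient** for T2W + ADC. The ADC map comes from
  a two-point DWI acquisition via the monoexponential decay model
  ADC = ln(S_b0 / S_b1000) / (b1 − b0). Features with inter-observer
  ICC(2,1) ≤ 0.6 under mask perturbation are screened out.
* **Signature construction** — coarse-to-fine selection on the primary
  cohort: univariate Cox screen, keep the top 20 % of features with
  p < 0.1, greedy |r| > 0.6 Pearson pruning, then LASSO-Cox
  (ℓ1-penalized partial likelihood) with the penalty chosen by
  cross-validated deviance. The signature score is
  RS = Σ_k β_k z_k over the selected normalized features; the primary
  cohort's median RS is the high/low cutoff, applied unchanged to
  validation cohorts.
* **Evaluation** — Kaplan–Meier curves and two-sided log-rank tests,
  Cox hazard ratios with 95 % CIs (Efron ties), time-dependent IPCW
  ROC AUC at 12/24/36 months, Harrell's C-index with CI, nomograms
  with calibration curves, decision-curve net benefit
  NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t), and continuous NRI / IDI for
  incremental value over a clinical-only model.
* **Treatment interaction** — subgroup chemotherapy-efficacy tables
  (HR of chemotherapy vs none per signature group × pT/pN stage cell)
  with Wald interaction p-values from Cox product terms.

## A worked example

```bash
python examples/03_fit_signature.py
```

builds a signature on a simulated 300-patient cohort with 3
informative features hidden among 80:

```
screen: 80 features -> coarse 13 -> pruned 13 -> selected 3
selected: ['feat00', 'feat01', 'feat02']
coefficients: [ 0.567 -0.224  0.231]
median cutoff: -0.034
high vs low DMFS log-rank p = 1.91e-23
```

Exactly the three planted features are recovered, and dichotomizing at
the median separates survival decisively.
The other examples cover cohort simulation (`01`), the 1240-feature
extraction (`02`), nomogram/NRI/IDI/decision-curve analysis (`04`) and
the chemotherapy-interaction table (`05`). The same workflow is
scriptable from a shell via the thin CLI:

```bash
radsurv --outdir study --seed 1 run-all
```

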