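"""Build a LASSO-Cox radiomic signature with the coarse-to-fine cascade.

Univariate Cox screen -> top-20% with p < 0.1 -> |r| > 0.6 correlation
pruning -> cross-validated LASSO-Cox.  The primary-cohort median score
becomes the portable high/low cutoff.
"""

import numpy as np
import pandas as pd

import radsurv as rs

rng = np.random.default_rng(0)
n = 300
X = rng.standard_normal((n, 80))
beta = np.zeros(80)
beta[:3] = [1.0, -0.8, 0.9]  # three informative features among 80
t_event = rng.exponential(1 / (0.02 * np.exp(X @ beta)))
censor = np.minimum(rng.exponential(80, n), 60)
idx = pd.Index([f"p{i:03d}" for i in range(n)], name="patient_id")
features = pd.DataFrame(X, columns=[f"feat{i:02d}" for i in range(80)], index=idx)
survival = pd.DataFrame(
    {"time_months": np.minimum(t_event, censor), "event": (t_event <= censor).astype(int)},
    index=idx,
)

model, screening = rs.build_signature(features, survival, seed=0)
print(f"screen: {len(screening.screen)} features -> coarse {len(screening.coarse_set)}"
      f" -> pruned {len(screening.pruned_set)} -> selected {len(model.selected_features)}")
print("selected:", model.selected_features)
print("coefficients:", np.round(model.coefficients, 3))
print(f"median cutoff: {model.cutoff:.3f}")

groups = rs.stratify(model, rs.score(model, features))
hi, lo = groups == "high", groups == "low"
stat, p = rs.logrank_test(
    survival.loc[hi.values, "time_months"], survival.loc[hi.values, "event"],
    survival.loc[lo.values, "time_months"], survival.loc[lo.values, "event"],
)
print(f"high vs low DMFS log-rank p = {p:.2e}")
print()
print("The selection stages are nested; a small p means the dichotomized "
      "signature separates survival, as intended when the planted features "
      "carry the hazard.")
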