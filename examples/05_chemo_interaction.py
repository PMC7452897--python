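"""Treatment-by-signature interaction analysis on a simulated cohort in
which adjuvant chemotherapy helps low-risk patients and harms high-risk
ones — the pattern the subgroup-efficacy table is designed to expose.
"""

import numpy as np
import pandas as pd

import radsurv as rs

rng = np.random.default_rng(4)
n = 2000
df = pd.DataFrame(
    {
        "adjuvant_ct": rng.integers(0, 2, n).astype(float),
        "risk_group": rng.choice(["high", "low"], n),
        "pN": rng.choice(["0", "1", "2"], n, p=[0.5, 0.3, 0.2]),
    }
)
high = (df.risk_group == "high").astype(float)
lp = 0.8 * high - 0.29 * df.adjuvant_ct + 0.82 * df.adjuvant_ct * high
t_event = rng.exponential(1 / (0.012 * np.exp(lp)))
censor = np.minimum(rng.exponential(250, n), 60)
df["time_months"] = np.minimum(t_event, censor)
df["event"] = (t_event <= censor).astype(int)

p_int = rs.interaction_test(df, "risk_group", "adjuvant_ct")
print(f"signature x chemotherapy interaction p = {p_int:.2e}")

table = rs.subgroup_efficacy_table(df, stage_variable="all")
cols = ["rs_group", "n_ct", "n_no_ct", "hr_ct_vs_noct", "hr_lower95",
        "hr_upper95", "logrank_p"]
print(table[cols].round(3).to_string(index=False))

print("\nby pathological nodal stage:")
table_pn = rs.subgroup_efficacy_table(df, stage_variable="pN")
print(table_pn[["stage_level"] + cols].round(3).to_string(index=False))
print()
print("HR > 1 in the high-signature rows (chemotherapy associated with "
      "worse DMFS) and HR < 1 in the low-signature rows recovers the "
      "planted qualitative interaction; the Wald p comes from the Cox "
      "product term.")
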