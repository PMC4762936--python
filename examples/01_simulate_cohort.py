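"""Generate a synthetic hypovolemic-shock cohort and inspect its marginals.

The generator emulates a study population of women with hypovolemic shock
after obstetric hemorrhage: worst-point pulse ~117, SBP ~90 (so shock
index ~1.3), outcome prevalences ~4.1% death / 6.6% SMO / 15.7% SMO-CI,
and ~10% missing diastolic pressure.
"""

import numpy as np

from vsalert import GeneratorParams, generate_cohort, outcome_table, write_cohort
from vsalert.derive import derive_table

params = GeneratorParams(n=958, seed=42)
cohort = generate_cohort(params)
write_cohort(cohort, "cohort.csv")

outcomes = outcome_table(cohort)
derived = derive_table(cohort)
si = derived["si"].dropna()

print(f"patients generated : {len(cohort)} (written to cohort.csv)")
for name in ("death", "smo", "smo_ci"):
    frac = outcomes[name].mean()
    print(f"prevalence {name:7s}: {100 * frac:5.1f}%  (n={outcomes[name].sum()})")
print(
    "worst-point SI      : median %.2f, IQR %.2f-%.2f"
    % (si.median(), np.quantile(si, 0.25), np.quantile(si, 0.75))
)
print(
    "\nEach patient carries a latent severity; vitals and the nested "
    "outcomes both load on it, so the shock index discriminates death "
    "with AUC ~0.87 by calibration."
)
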