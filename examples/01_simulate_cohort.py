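"""Generate a synthetic donor cohort and inspect its summary statistics.

The generator draws lognormal actual graft weights (AGW), per-method volume
estimates with multiplicative bias 1/c and lognormal noise, and truncated
normal recipient weights.
"""

import numpy as np

from graftcalib import CohortParams, generate_cohort, write_cohort

params = CohortParams(n=100)
cohort = generate_cohort(params, seed=1)
write_cohort(cohort, "cohort.csv")

agw = cohort.agw()
print(f"n = {cohort.n} donors, methods = {cohort.methods}")
print(f"AGW mean +/- SD: {agw.mean():.1f} +/- {agw.std(ddof=1):.1f} g "
      "(generator targets 783.7 +/- 163.5)")
for m in cohort.methods:
    egv = cohort.right_volumes(m)
    r = np.corrcoef(egv, agw)[0, 1]
    print(f"  {m:15s} mean EGV {egv.mean():7.1f} mL   r(EGV, AGW) = {r:.3f}")
# Each method overestimates AGW by 1/true_factor on average; the correlation
# reflects the calibrated measurement noise (target r ~ 0.82).
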