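"""Estimate dry-weight correction factors by L1 grid search.

The factor grid spans 0.80-0.95 in steps of 0.01; the objective is the
total absolute difference sum(|c*EGV - AGW|).  The exact continuous
minimiser (the EGV-weighted median of AGW/EGV ratios) is shown next to the
grid argmin.
"""

from graftcalib import (
    CohortParams,
    calibrate_method,
    exact_l1_factor,
    generate_cohort,
)

cohort = generate_cohort(CohortParams(n=100), seed=1)
agw = cohort.agw()
print(f"{'method':16s} {'grid c':>7s} {'exact c':>8s} {'sum|c*EGV-AGW|':>15s}")
for m in cohort.methods:
    egv = cohort.right_volumes(m)
    res = calibrate_method(egv, agw, method=m)
    exact = exact_l1_factor(egv, agw)
    print(f"{m:16s} {res.c_opt:7.2f} {exact:8.4f} {res.objective_at_opt:15.2f}")
# The grid argmin sits within one 0.01 step of the exact L1 minimiser; the
# generating factors were 0.89 / 0.82 / 0.88.
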