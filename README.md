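# graftcalib

Calibration and agreement analysis for preoperative liver graft volumetry
in living donor liver transplantation (LDLT).

## The problem

Before a living donor's right liver lobe is transplanted, its size is
estimated from CT volumetry (EGV, in mL). The gold standard — the actual
graft weight (AGW, in grams) weighed after procurement — is only known in
the operating room. CT systematically overestimates the graft: blood
content, perfusion state and segmentation boundaries all inflate the
volume. Surgical teams therefore apply a *dry-weight correction factor*
`c < 1` to the estimate, and the right factor differs between volumetry
software products.

`graftcalib` is for transplant-surgery and imaging researchers who want to
calibrate such factors against their own cohort and quantify how well each
volumetry method predicts graft weight. It provides:

* **Calibration** — for each method, `c` is chosen to minimise the total
  absolute difference

  `S(c) = Σᵢ |c·EGVᵢ − AGWᵢ|`

  over a factor grid (0.80–0.95 in 0.01 steps by default). `S` is convex
  piecewise-linear in `c`; its continuous minimiser is the EGV-weighted
  median of the per-donor ratios `AGWᵢ/EGVᵢ`, which the package also
  computes exactly and uses as the oracle for the grid search.
* **Accuracy** — per-donor error ratio `(EGV − AGW)/AGW × 100%`, with the
  exact before/after-correction transform
  `mean_post = (c·(1 + mean_pre/100) − 1)·100`, `sd_post = c·sd_pre`.
* **Agreement** — Pearson r with Fisher-z CI, OLS regression of AGW on EGV
  (R², residual SE), modified Bland–Altman limits of agreement (reference
  axis = AGW), ICC(A,1) (two-way model, absolute agreement, single
  measures), and Steiger's z for comparing two methods' correlations with
  AGW.
* **Safety screening** — graft-to-recipient weight ratio
  (GRWR = graft g / recipient g × 100%, flag below 0.8%) and donor remnant
  ratio (flag below 30% of total liver volume).
* **Synthetic cohorts** — a donor-cohort generator with lognormal AGW,
  method-specific multiplicative bias `1/c` and calibrated lognormal noise,
  so the whole pipeline is testable without patient data.

## Worked example

```python
from graftcalib import CohortParams, generate_cohort, calibrate_method, exact_l1_factor

cohort = generate_cohort(CohortParams(n=100), seed=1)   # true factors 0.89/0.82/0.88
agw = cohort.agw()
for m in cohort.methods:
    egv = cohort.right_volumes(m)
    res = calibrate_method(egv, agw, method=m)
    print(m, res.c_opt, round(exact_l1_factor(egv, agw), 4), round(res.objective_at_opt, 2))
```

prints

```
automated 0.89 0.8968 9535.6
semi_automated 0.81 0.8152 8298.87
manual 0.89 0.8845 8218.62
```

— the grid argmin (first number) sits within one 0.01 step of the exact L1
minimiser (second number); the third number is the total absolute
difference `S(c)` in g at the optimum. At n = 100 the estimate scatters by
roughly ±0.015 around the generating factor, so 0.81 against a true 0.82
is expected sampling noise.

The agreement battery on the corrected semi-automated estimates
(`examples/03_agreement_battery.py`) prints

```
correction factor c = 0.81
error ratio:  20.89% +/- 16.82%  ->  -2.08% +/- 13.62%
Pearson r = 0.771 (95% CI 0.677-0.840)
AGW = 241.5 + 0.702 x EGV   (R^2 = 0.595, SE = 95.5 g)
Bland-Altman: MD -19.1 g, LOA -228.5 to 190.3 g
ICC(A,1) = 0.764 (95% CI 0.668-0.835)
```

— correction moves the mean error from a ~21% overestimate to about −2%
and shrinks its SD by the factor c; r and R² are invariant under scaling.

The `examples/` directory holds one short script per capability
(simulation, calibration, agreement, safety screening, full report). A
thin CLI mirrors them:

```bash
graftcalib simulate --n 100 --seed 1 --out cohort.csv
graftcalib calibrate --input cohort.csv --method semi_automated --grid-out grid.csv
graftcalib report --input cohort.csv --out-dir report_out
```

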