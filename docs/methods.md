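# Methods

## Calibration model

The calibration target is a single multiplicative dry-weight correction
factor per volumetry method. Given per-donor pairs (EGVᵢ, AGWᵢ), the
objective is the total absolute difference

    S(c) = Σᵢ |c·EGVᵢ − AGWᵢ|,

i.e. L1 regression of AGW on EGV through the origin. S is convex and
piecewise-linear in c with breakpoints at the ratios rᵢ = AGWᵢ/EGVᵢ, and
its minimiser is the weighted median of the rᵢ with weights EGVᵢ.
`exact_l1_factor` computes this by sorting the ratios and walking the
cumulative weight to the half-total crossing (O(n log n)); when the
minimum is attained on a flat interval (the crossing lands exactly on a
breakpoint) the interval's lower endpoint is returned.

The grid search (`correction_grid` / `optimal_factor`) evaluates S on
c = lo + k·step for integer k (defaults 0.80–0.95, step 0.01, 16 points).
Grid points are built by integer index rather than repeated addition so no
floating-point drift accumulates, and each is snapped to the decimal value
the index represents. Ties — S is flat between adjacent breakpoints — are
broken toward the smallest factor, the conservative choice for donor
safety (a smaller factor predicts a smaller graft), and the tie count is
reported. An argmin at either grid end sets `at_boundary` instead of
silently extending the range; widening the grid is the caller's decision.

Units: volumes (mL) and weights (g) are treated as numerically
interchangeable before correction (the 1 mL = 1 g working premise common
in this field); the objective is reported unitless.

## Accuracy and agreement statistics

* **Error ratio** (EGV − AGW)/AGW × 100% per donor, summarised as mean ±
  sample SD (n−1 denominator everywhere in the package). Applying a factor
  c transforms each ratio through 1 + r/100 ↦ c·(1 + r/100), so the
  summary transforms exactly: mean_post = (c·(1 + mean_pre/100) − 1)·100,
  sd_post = c·sd_pre. `corrected_error_summary` exposes this identity;
  the pipeline's post-correction summaries satisfy it to machine
  precision by construction.
* **Pearson r** with the Fisher-z interval tanh(atanh r ± z_α/√(n−3));
  a perfect correlation degenerates to a clamped point interval with a
  logged warning. r, R² and the CI are invariant under positive scaling of
  either variable, hence identical pre- and post-correction.
* **Regression**: OLS of AGW (y) on EGV (x); R² = squared Pearson r;
  residual SE = √(SSE/(n−2)) in grams.
* **Modified Bland–Altman**: differences est − AGW summarised as mean
  difference and mean ± 1.96·SD limits of agreement. "Modified" refers to
  using the gold-standard AGW, not the pairwise mean, as the reference
  axis; the summary statistics do not depend on that choice. The 1.96
  multiplier is configurable.
* **ICC**: two-way model, absolute agreement, single measures — McGraw &
  Wong's ICC(A,1),
  (MS_rows − MS_err)/(MS_rows + (k−1)MS_err + (k/n)(MS_cols − MS_err)),
  k = 2 — with the F-based confidence interval, computed via
  `pingouin.intraclass_corr`. The consistency variant ICC(C,1) is a
  config option. The test suite checks the implementation against an
  independent brute-force two-way ANOVA mean-squares computation. When the
  interval is undefined (perfect agreement gives an infinite F) it is
  clamped to the point estimate with a warning.
* **Comparing dependent correlations**: two methods' correlations with the
  shared AGW are compared with Steiger's z (Fisher-z difference with the
  Dunn & Clark covariance and Steiger's pooled-correlation
  simplification); two-sided p from the standard normal. No
  multiple-testing adjustment is applied across the method pairs; raw p
  values are reported.

The agreement battery runs on corrected estimates by default (a
`pre_correction` flag evaluates the raw ones); correction only affects the
statistics that are not scale-invariant (error ratios, regression
intercept/slope/SE, Bland–Altman, ICC).

## Safety screening

GRWR = graft weight (g) / (recipient weight (kg) × 1000) × 100%. The
small-for-size flag is raised when GRWR falls strictly below the threshold
(default 0.8%; a GRWR of exactly 0.8% is acceptable). Predicted GRWR uses
the corrected estimate c·EGV and therefore scales exactly by c relative to
the uncorrected prediction. Remnant ratio = 100% − right/total × 100%,
flagged strictly below 30% by default (configurable to the stricter 40%
bound some centres use). Both per-donor mean-of-ratios and ratio-of-means
forms of the right/total percentage are computed and labelled in reports,
since the two differ in general. No special-casing of the caudate lobe is
attempted; totals are taken as the data provider folded them.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any particular scanner or software:

* AGW ~ LogNormal, moment-matched so the linear mean/SD equal the targets
  (defaults 783.7/163.5 g): σ² = ln(1 + (sd/mean)²), μ = ln(mean) − σ²/2.
* EGV_m = (AGW/c_m)·exp(ε_m) with ε_m ~ Normal(−σ_m², σ_m²). The −σ_m²
  centring makes the population minimiser of S(c) equal c_m exactly: the
  weighted-median estimand is the ratio quantile under EGV-weighting,
  which tilts a zero-mean lognormal noise by exp(ε) and would otherwise
  place the L1 optimum at c_m·exp(−σ_m²) — a ~0.017 downward shift at
  σ = 0.144 that would dominate the estimator's sampling error. With the
  centring the exact-L1 estimate at n = 2000 has mean absolute error of
  about 0.003. At σ = 0 the centring vanishes and c_m·EGV = AGW holds to a
  unit in the last place.
* Noise SDs come from a target Pearson correlation via
  σ_m = σ_A·√(1/r² − 1) (exact for the correlation of the logs; the
  linear-scale r at these coefficients of variation is within ~0.005 of
  the target — simulated r ≈ 0.816 for a 0.82 target). Default target
  r = 0.82, giving σ_m ≈ 0.144 for all three default methods
  (automated/semi_automated/manual with true factors 0.89/0.82/0.88).
* Total liver volume is right lobe × 1.553 (right/total ≈ 64.4%), a fixed
  ratio — the generator does not model independent remnant variation.
* Recipient weight ~ Normal(63.2, 11) kg truncated at 35 kg, independent
  of AGW; these values put the mean GRWR near 1.24% with SD ≈ 0.35.
  The truncation bound only prevents non-physiologic recipients.
* One integer seed drives everything through a `SeedSequence`; per-method
  sub-streams are spawned in method order so adding a method leaves the
  other draws unchanged.

What the generator does *not* emulate: inter-observer variability,
density/steatosis heterogeneity, correlated errors between methods beyond
their shared dependence on AGW, dissection-line mismatch, or any
dependence of recipient weight on graft size. Passing tests demonstrate
that the statistical machinery is correct under this generative model,
not that any particular software's estimates behave this way.

## Numerical choices

* Tie detection on the grid uses a 1e-9 relative tolerance on the
  objective (flat stretches are exact in real arithmetic but not in
  floats).
* Factors are stored at full precision and rounded only at render time
  (2 dp for factors, 2 dp for percentages and grams, 3 dp for
  correlations).
* Sample SD (n−1) is used throughout, including the Bland–Altman limits.
* Percent quantities are carried as fractions internally where convenient
  and converted at the interface.
* Degenerate inputs fail loudly: constant series for correlation, constant
  x for regression, zero total variance for ICC, |r| = 1 for Steiger's
  test (the pipeline skips that pair's comparison with a warning rather
  than failing the whole report).

## Problem sizes

The test suite and acceptance script use cohorts of n = 100 (the typical
single-centre study size and the generator default), n = 2000 for
stochastic factor-recovery checks (200 replicate seeds, mean absolute
error ≤ 0.01), and n = 10⁵ for Monte-Carlo moment and coverage checks
(AGW mean within 1%, SD within 2%, GRWR mean within 5% of targets;
Bland–Altman coverage 95% ± 1%).

## Known limitations

* The calibration estimates a single cohort-wide factor; covariate-
  dependent or per-donor factors are out of scope.
* At n = 100 and σ ≈ 0.144 the factor estimate has a sampling SD of about
  0.015, so single-cohort grid recoveries land within ±0.02 of the truth
  in roughly 85% of runs — an irreducible property of the estimator at
  that sample size, not an implementation artefact.
* The Fisher-z interval and ICC confidence bounds assume bivariate
  normality / two-way ANOVA assumptions; heavy-tailed volumetry errors
  will make them approximate.
* L2 or quantile-general calibration, repeated-measures comparisons of
  measurement times, and image segmentation itself are out of scope.
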