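# Methods

## Signal models

A voxel's diffusion-weighted magnitude signal over b-values
`b` (s/mm²) is modelled two ways:

* **Mono-exponential**: `S(b) = S0 · exp(-b·ADC)`.  The apparent diffusion
  coefficient summarises all water pools with one rate and is the quantity
  clinical DWI reports (in 10⁻³ mm²/s).
* **Three-compartment (restriction spectrum)**:
  `S(b) = S0 · (f1·e^{-b·D1} + f2·e^{-b·D2} + f3·e^{-b·D3})`, `D1 < D2 < D3`,
  with volume fractions `f1, f2, f3 ≥ 0`, `f1+f2+f3 = 1` for the
  restricted, hindered and free pools.  The compartmental diffusivities are
  held fixed at 1.0, 2.0 and 3.0 ×10⁻³ mm²/s — standard literature values —
  which keeps the model linear in the amplitudes, prevents overfitting on a
  12-point schedule and makes fractions comparable across voxels and
  patients.  The diffusion is treated as isotropic (trace-weighted);
  no tensor or direction modelling.

The default acquisition schedule is 0, 25, 50, 100, 150, 200, 400, 600,
800, 1000, 1500, 2000 s/mm².  Fractions are carried in [0, 1] internally
and printed ×10⁻² only at the report layer; b·D is dimensionless by
construction.

**Noise.**  Magnitude MR noise is Rician: `sqrt((s+g1)² + g2²)` with
independent zero-mean Gaussians `g1, g2` of standard deviation σ (a single
σ for all b-values by default; per-b σ would model varying excitation
averages, which we do not attempt).  At high SNR this approaches additive
Gaussian noise; at low SNR it produces the well-known positive floor.

## Fitting

* **ADC**: unweighted ordinary least squares of `ln S` on `b` over all
  strictly positive amplitudes, ADC = −slope, S0 = exp(intercept).  Exact
  on noiseless mono-exponential input.  Voxels with fewer than two
  positive amplitudes, or a non-positive fitted ADC, are excluded from the
  ADC map mask.
* **Compartment fractions**: non-negative least squares (Lawson–Hanson,
  `scipy.optimize.nnls`) of the raw amplitudes against the basis
  `exp(-b·D_i)`; `S0` is recovered as the amplitude sum and fractions as
  amplitudes over that sum.  The simplex constraint therefore holds
  *exactly* for every fitted voxel without a second constrained solve, and
  no division by the noisy b=0 measurement occurs.  All-zero voxels are
  unfittable and drop out of the mask; voxels with some zero amplitudes
  remain (the linear model is defined there, unlike the log transform).
* No Rician bias correction is applied before fitting and no spatial
  regularisation is used; maps are strictly per voxel.  At SNR 50 the
  resulting bias is small against the fraction scale (the noise-robustness
  regression test bounds the mean absolute f1 error by 0.05 at
  f = (0.8, 0.1, 0.1)); at substantially lower SNR the noise floor
  inflates high-b amplitudes and biases fractions toward slower
  compartments.  This is a known limitation.

A useful structural fact, asserted in the tests as a simulation property:
the mono-exponential ADC fitted to a three-compartment signal increases
monotonically as the restricted fraction decreases — ADC and f1 are
coupled views of the same spectrum, which is why both appear (with
opposite signs) as subtype discriminators.

## Synthetic data

**Phantoms** place an elliptical "lesion" with constant or linearly ramped
ground-truth fractions on a free-water background (f = (0, 0, 1)), render
the stack through the forward model and add Rician noise.  They exist to
close the loop: at σ = 0 the fitted maps reproduce the generating field to
solver precision, and ROI means of a linear ramp equal the midpoint.

**Cohorts** draw 30 SCC and 67 AC patients by default.  Per-group
marginals (units as reported clinically):

| variable | SCC | AC | family |
|---|---|---|---|
| age (y) | 62.47 ± 8.85 | 61.51 ± 8.01 | normal |
| f1 | 0.671 ± 0.173 | 0.863 ± 0.130 | truncated normal on [0, 1] |
| ADC (10⁻³ mm²/s) | 1.11 ± 0.35 | 1.37 ± 0.25 | truncated normal (> 0) |
| f2 | 0.087 (0.016, 0.129) | 0.0024 (0, 0.043) | log-normal (median, IQR) |
| f3 | 0.214 (0.119, 0.337) | 0.083 (0.0001, 0.194) | log-normal (median, IQR) |
| diameter (cm) | 3.45 (2.38, 4.50) | 2.00 (1.50, 3.00) | log-normal (median, IQR) |
| SUVmax (g/cm³) | 9.93 (5.30, 12.80) | 3.77 (1.88, 6.64) | log-normal (median, IQR) |
| male | 25/30 | 40/67 | Bernoulli |
| smoking | 21/30 | 21/67 | Bernoulli |

Design choices that were genuinely open:

* **Truncated-normal calibration.**  The stated mean/SD are treated as the
  moments of the *truncated* distribution: the location is solved by a
  root find so the truncated mean matches the target exactly, and the
  scale so the truncated SD matches as closely as the family allows.
  Naive truncation at the stated location would bias the AC restricted
  fraction mean down by ≈ 0.035 (the target sits ≈ 1 SD below the upper
  bound).  Large-n sample moments therefore converge to the stated values,
  which the tests verify.
* **Median/IQR → log-normal.**  `mu = ln(median)`,
  `sigma = (ln q3 − ln q1)/(2·z₀.₇₅)`.  Where a lower quartile is reported
  as 0 (a rounding artefact of small fractions) the upper half-spread
  `(ln q3 − ln median)/z₀.₇₅` is used, and σ for the fraction variables is
  capped at 2.5 so draws remain meaningful.
* **Simplex coupling.**  Three marginals cannot simultaneously hold under
  an exact simplex.  f1 — the headline discriminator — keeps its marginal;
  provisional log-normal f2 and f3 draws are rescaled, preserving their
  ratio, to sum to 1 − f1.  Consequently the *ratio* structure and group
  ordering of f2/f3 are faithful while their marginal spread is not
  exactly the printed IQR.
* **Two modes.**  `summary` mode draws ADC and fractions directly from the
  tables above (fast; variables independent within group).  `image` mode
  renders one phantom per patient at SNR 50 (σ = S0/50), fits it and uses
  the ROI means — physically consistent, and ADC is then *derived* from
  the same signal as the fractions rather than drawn independently.  At
  σ = 0 the two routes agree exactly on the fraction columns.

What passing tests on these cohorts do **not** show about real data: the
generator models marginals only, so predictors are independent within
group, whereas in patients ADC, fractions and SUVmax are correlated.
Independent signals combine more favourably, so the combined-model AUC on
synthetic cohorts (typically ≈ 0.94–0.96 at the default separations) sits
above what correlated clinical data would give; the qualitative claim the
pipeline supports is that the combined model beats every single predictor,
not the specific AUC value.

## Cohort statistics

Conventions are fixed so that two-group summary statistics reproduce
published reference values to printed precision:

* Welch (unequal-variance) t, two-sided, with Satterthwaite df; a
  moments-based overload runs the test directly from printed mean/SD/n.
  (The pooled-variance t does not reproduce the reference age and f1
  statistics; Welch does.)
* Pearson χ² on 2×2 tables without Yates continuity correction, df = 1.
* Mann–Whitney U via midranks; tie-corrected normal approximation, no
  continuity correction.  Exact permutation p-values are out of scope.
* Odds ratios as the cross-product with Wald intervals on the log scale;
  zero cells are an error, never silently corrected.
* ICC(2,1) — two-way random effects, absolute agreement, single measure —
  from the ANOVA decomposition.  Agreement above 0.75 is the customary
  reliability bar.  The pipeline itself has a single synthetic "reading"
  per patient, so ICC is exercised by the unit tests only.
* Automatic test selection for continuous variables: Shapiro–Wilk in each
  group at α = 0.05; both normal → Welch t, otherwise Mann–Whitney.
* All p-values two-sided; significance at 0.05 throughout.

## Predictive modelling

The positive class is SCC; reported probabilities are P(SCC).  Fraction
predictors enter the model ×10⁻² and ADC in 10⁻³ mm²/s, so odds ratios are
per percentage point and per 10⁻³ mm²/s respectively.

* **Logistic regression**: Newton/IRLS on the full likelihood, gradient
  tolerance 10⁻⁸, at most 100 iterations, intercept always included; Wald
  SEs from the observed information.  Rank deficiency raises a
  collinearity error; perfect separation raises an error naming the
  predictor that best separates the classes on its own (separation is also
  re-checked at numerical convergence, since a separated likelihood can
  drive the gradient to zero while the coefficients diverge).
* **Univariate screen**: one single-predictor fit per candidate;
  candidates with p < 0.05 enter the joint model.  Because the fraction
  triple sums to 1 exactly, at most two of f1/f2/f3 can enter jointly; the
  pipeline drops the weakest by univariate p.  If the joint model is
  completely separated the pipeline removes the named predictor and
  refits, as an analyst requiring interpretable odds ratios would.
  Optional backward elimination drops the largest-p predictor above 0.05
  until all remaining are significant.
* **ROC**: empirical AUC = concordance probability with half credit for
  ties (hence exactly U/(n₁n₂) of the Mann–Whitney statistic — asserted as
  a cross-module identity).  Cutoff candidates lie midway between adjacent
  observed scores; the Youden-maximal cutoff is reported, ties broken
  toward higher sensitivity.  The AUC interval uses the DeLong variance
  (normal on the AUC scale, clipped to [0, 1]); paired AUCs are compared
  with DeLong's structural-components test computed from midranks.
* **Bootstrap validation**: B = 1000 resamples with replacement,
  stratified by outcome (both classes always present).  Per resample the
  model is refitted and its AUC measured on the resample and on the
  original cohort; optimism is the mean difference and
  corrected = apparent − optimism.  Both the bootstrap-mean AUC (with a
  percentile interval) and the optimism-corrected AUC are reported, since
  single published "bootstrap AUC" figures are usually ambiguous between
  the two.  Resample refits tolerate separation (only the predicted
  ranking enters the AUC); hard failures are logged and at most 5% of B
  are allowed.
* **Calibration**: equal-count decile curve plus a logistic recalibration
  of outcomes on logit(p); slope 1 / intercept 0 is ideal.  Note that
  in-sample recalibration of a freshly fitted MLE is exactly (1, 0) — an
  identity, not evidence; out-of-sample calibration is what the bootstrap
  addresses.
* **Decision curves**: net benefit `TP/n − (FP/n)·pt/(1−pt)` against
  treat-all and treat-none references over a 0.01–0.99 threshold grid.

## Numerical notes and degenerate inputs

Fraction triples within 10⁻⁹ of the simplex are renormalised, larger
violations rejected.  Empty ROIs, all-zero voxels, single-class outcomes,
zero-margin tables and zero-variance ICC inputs raise typed errors rather
than returning NaNs.  Every stochastic component takes an explicit integer
seed; the full pipeline writes a manifest (config hash, seed, version) and
is byte-reproducible for a fixed config.

## Problem sizes

Default analyses use the study-scale cohort (30 + 67) with B = 1000
bootstrap resamples.  The test suite exercises larger designs where a
statistical property demands it (10⁴–10⁵ draws for moment convergence,
10⁴ null replicates for type-I error, 100 replicates at n = 5000 for
coefficient coverage) and a 24×24 (or 12×12) phantom grid for imaging
round trips — sizes chosen so each property is measured with adequate
Monte Carlo precision.

## Known limitations

Compartmental diffusivities are fixed, not estimated; no more than three
compartments.  No Rician bias correction.  No inter-variable correlation
in the cohort generator beyond the simplex coupling.  No image
registration, segmentation or PET processing: ROI masks and SUVmax are
inputs.  Printed-value reproduction is limited to statistics computable
from group summaries; voxel-level agreement with any particular vendor's
fitting toolchain is not claimed beyond the models as written.
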