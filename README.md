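# rsifit

Restriction spectrum imaging (RSI) decomposes the diffusion-weighted MRI
signal of a voxel into restricted (intracellular), hindered (extracellular)
and free-water compartments.  Because squamous cell carcinoma (SCC) and
adenocarcinoma (AC) — the two major non-small-cell lung cancer (NSCLC)
subtypes — differ in cellularity and extracellular architecture, the
compartment fractions, together with the apparent diffusion coefficient
(ADC), PET SUVmax and clinical covariates, can discriminate the subtypes
noninvasively.

`rsifit` implements that whole analysis as a reusable, fully synthetic-data
testable pipeline for imaging scientists and biostatisticians:

* **Forward models.**  Mono-exponential decay `S(b)/S0 = exp(-b·ADC)` and
  the three-compartment model
  `S(b) = S0·(f1·e^{-b·D1} + f2·e^{-b·D2} + f3·e^{-b·D3})`,
  with fixed diffusivities `D1 < D2 < D3` (1.0, 2.0, 3.0 ×10⁻³ mm²/s) and
  Rician measurement noise, over a 12-point b-value schedule
  (0–2000 s/mm²).
* **Voxelwise fitting.**  scikit-learn-style estimators: log-linear OLS for
  ADC (`MonoExponentialADC`) and non-negative least squares for the
  compartment amplitudes (`RestrictionSpectrumNNLS`), which makes
  `f1+f2+f3 = 1` hold exactly by construction.
* **Synthetic data.**  Elliptical lesion phantoms with known ground truth,
  and two-group patient cohorts (default 30 SCC / 67 AC) whose per-group
  marginals emulate a clinical NSCLC cohort.
* **Cohort statistics.**  Welch t, Mann–Whitney U (tie-corrected, no
  continuity correction), Pearson χ² (no Yates correction), Wald odds
  ratios, ICC(2,1), and a Shapiro–Wilk-gated automatic test selector.
* **Predictive modelling.**  IRLS logistic regression with Wald inference
  and explicit separation/collinearity diagnostics, empirical ROC with
  Youden cutoffs, DeLong AUC comparison, 1000-sample optimism-corrected
  bootstrap validation, calibration curves and decision-curve analysis.

## Worked example

```python
import numpy as np
import rsifit as rf

# simulate one tumour voxel and invert it
sched = rf.BValueSchedule()                      # 0 ... 2000 s/mm^2
truth = rf.CompartmentParams(f1=0.70, f2=0.10, f3=0.20, S0=1000.0)
signal = rf.tri_exp_signal(truth, sched.as_array)
noisy = rf.add_rician_noise(signal, rf.NoiseSpec(sigma=20.0, seed=7))

est = rf.fit_rsi(rf.VoxelSignal(sched, tuple(noisy)))
print("fractions:", np.round(est.fractions, 3), " S0:", round(est.S0, 1))
adc = rf.fit_adc(rf.VoxelSignal(sched, tuple(noisy)))
print("ADC (1e-3 mm^2/s):", round(adc.ADC * 1e3, 3))

# two-group comparison on a synthetic cohort
cohort = rf.generate_cohort(n_scc=30, n_ac=67, seed=1)
res = rf.welch_t_samples(100 * cohort.loc[cohort.group == "SCC", "f1"],
                         100 * cohort.loc[cohort.group == "AC", "f1"])
print("Welch t on f1:", round(res.statistic, 3), " p:", f"{res.p_value:.2e}")
```

prints

```
fractions: [0.741 0.    0.259]  S0: 995.2
ADC (1e-3 mm^2/s): 1.141
Welch t on f1: -5.28  p: 4.12e-06
```

At SNR 50 a single voxel's fractions carry a few percent of noise (here the
small hindered fraction is absorbed into its neighbours — ROI averaging in
`fit_parameter_maps`/`summarize_roi` is what stabilises per-patient values),
while the cohort-level restricted-fraction difference between subtypes is
detected with a strongly significant Welch t.

The same workflow is available from the shell:

```bash
rsifit simulate-cohort --n-scc 30 --n-ac 67 --seed 1 --out cohort.csv
rsifit analyze descriptive --cohort cohort.csv --out table.csv
rsifit run --seed 1 --bootstrap 1000 --out report/
```

`rsifit run` writes a full report bundle (descriptive table, univariate and
multivariate logistic tables, ROC summaries with DeLong comparisons against
the combined model, bootstrap validation, calibration and decision-curve
point tables, and a manifest); identical seed and config reproduce it
byte-for-byte.

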