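# adpkdval

External validation and updating of kidney-volume-based eGFR prediction
models for autosomal dominant polycystic kidney disease (ADPKD), packaged
with a synthetic longitudinal cohort simulator so the entire analysis is
reproducible without any patient data.

## The problem

ADPKD progresses from enlarging, cyst-filled kidneys to loss of filtration
function. The Mayo imaging classification turns a single measurement of
height-adjusted total kidney volume (HtTKV, ml/m) plus the patient's age
into one of five ordinal risk subclasses, 1A–1E, via the yearly growth rate
`r` implied by exponential growth from a theoretical 150 ml/m at birth:

    HtTKV = 150 · (1 + r)^age,   class bins at r = 1.5, 3.0, 4.5, 6 %/yr.

On top of the classification sits a linear mixed model that predicts eGFR
(ml/min/1.73 m²) after `t` years of follow-up from baseline covariates:

    eGFR_it = x_it'β + b_i·t + ε_it,
    b_i ~ N(0, σ_b²),  ε_it ~ N(0, σ_e²),

where `x_it` holds log₂HtTKV (or the subclass indicators), baseline age,
sex, baseline eGFR, a linear term in `t`, and the interaction of `t` with
every baseline predictor; `b_i` is a subject-specific slope.

This package implements, for users who want to validate or locally
recalibrate such a model on their own cohort:

- **Risk classification** — subclass assignment, age-dependent class
  boundary curves, and class-transition summaries over follow-up.
- **Frozen-coefficient external validation** — apply a developed model
  unchanged and score it with Bland–Altman bias and 95% limits of
  agreement, P30, two R² variants, correlation, AIC, and the continuous
  ranked probability score (CRPS) of the Gaussian predictive distribution.
- **Partial model updating** — refit *only* the kidney-volume
  coefficient(s) on new data via an offset likelihood, either adding a
  second HtTKV measurement per patient (Model 1) or using the time-varying
  HtTKV at every visit (Model 2), with or without an HtTKV×years
  interaction, evaluated by patient-level five-fold cross-validation.
- **Multiple imputation** of missing HtTKV under a multivariate-normal
  data-augmentation (MCMC) sampler, with Rubin pooling.
- **A seeded cohort simulator** that emulates the longitudinal structure of
  a contemporary European ADPKD study (median age 34 y, eGFR 82, HtTKV 497
  ml/m, second visit at 6–12 months then annual, 3% missing HtTKV) and of
  an older, larger-kidney development population.

## Worked example

```python
import adpkdval as av

dev = av.generate_cohort(av.development_config(376, seed=20240901))
val = av.generate_cohort(av.GeneratorConfig(n_patients=214, seed=20240902))

frozen = av.fit_development_model(dev, av.MODE_CONTINUOUS)
preds = av.predict_cohort(frozen, val)
report = av.validation_report(
    "validation_tkv", preds["egfr_obs"], preds["egfr_pred"], pred_sd=preds["pred_sd"]
)
print(f"R2 {report.r2:.3f}  bias {report.bias:.2f}  "
      f"LoA ({report.loa_low:.1f}, {report.loa_high:.1f})  "
      f"P30 {report.p30:.1f}%  CRPS {report.crps:.2f}")

updated = av.cross_validated_report(val, frozen, av.UPDATE_MODEL2, seed=77)
print(f"updated model 2: bias {updated.bias:.2f}  CRPS {updated.crps:.2f}")
```

prints

```
R2 0.710  bias 4.22  LoA (-16.6, 25.1)  P30 90.7%  CRPS 6.04
updated model 2: bias 3.10  CRPS 5.72
```

Reading: the externally developed model explains ~72% of eGFR variance on
the new cohort but under-predicts by ~4 ml/min/1.73 m² (the two cohorts
differ in age, kidney size and TKV measurement); refitting just the
kidney-volume coefficient on local data shrinks the bias and improves the
probabilistic score (lower CRPS is better).

The same analysis as a narrative pipeline lives under `analysis/`
(`01_simulate_cohorts.py` … `06_impute_missing.py`, writing their tables to
`results/`), and as a CLI:

```sh
adpkdval simulate --seed 1 --n 214 --out cohort.csv
adpkdval classify cohort.csv --out classes.csv
adpkdval run --seed 1 --out results/run1
```

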