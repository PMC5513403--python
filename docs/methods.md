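# Methods

## The prediction model

eGFR after `t` years of follow-up is modelled as a linear mixed model

    eGFR_it = x_it'β + b_i·t + ε_it,
    b_i ~ N(0, σ_b²),  ε_it ~ N(0, σ_e²),

with baseline predictors `x` = {log₂HtTKV or risk-subclass indicators
(1A reference), baseline age in years (uncentered), sex (female = 1,
male = 0), baseline eGFR}, a linear term in `t`, and the interaction of `t`
with every baseline predictor. The random effect is a subject-specific
slope on `t` only; a random-intercept variant is available behind
`random_intercept=True` for sensitivity analysis, but the default follows
the view that between-patient differences in *level* are already carried
by baseline eGFR as a covariate, leaving the *rate of decline* as the
subject-specific quantity.

Fitting is maximum likelihood through `statsmodels.MixedLM` (its default
optimizer; L-BFGS collapses the random-slope variance to a degenerate
zero on this likelihood and is not used). ML rather than REML is the
default because AIC comparisons across fixed-effect structures are only
meaningful under ML; `reml=True` is available. On data with an exactly
linear response (zero noise) the fit degenerates gracefully: the
coefficients equal the OLS solution and both variance components go to
numerical zero.

The population-level prediction for a new patient sets `b_i` to its zero
mean; the predictive SD is the marginal `sqrt(t²σ_b² + σ_e²)` (a
conditional, residual-only variant exists behind a flag). This marginal SD
feeds the Gaussian CRPS.

## Risk subclassification

A patient of age `a` with HtTKV `v` is assigned the growth rate solving
`150·(1+r)^a = v`; the 150 ml/m birth anchor is exposed as a parameter.
Rates are binned at 1.5, 3.0, 4.5 and 6 %/yr into classes 1A–1E.
Boundaries are left-closed into the higher class (exactly 1.5 %/yr is 1B):
the published range descriptions overlap at the endpoints, so one
convention had to be fixed. Class transitions compare the baseline class
with the class at the **last visit with a non-missing HtTKV**, evaluated at
age `a + t`; patients with no measured follow-up HtTKV are excluded from
the denominator.

## Partial updating

Updating re-estimates only the kidney-volume coefficient(s) while every
other regression coefficient, including the intercept, stays at its
development value. Implementation: the frozen terms form an offset
`o_it = Σ_frozen β_j x_ijt`, and the mixed model is refit on `y_it − o_it`
with only the free columns as fixed effects. This is algebraically
identical to a fully constrained refit (verified in the test suite against
an independent joint constrained-ML optimizer to ~1e-9 on the free
coefficient). Variance components are always re-estimated: freezing
applies to regression coefficients, and recalibrated predictive variances
are precisely what a local update should deliver.

Two update designs:

- **Model 1 (two measurements)**: the earliest follow-up visit with a
  measured HtTKV contributes an additional `log₂HtTKV_second` term (the
  published description does not say whether the second measurement adds to
  or replaces the baseline term; adding is the default here, and the free
  set is {baseline log₂HtTKV, second log₂HtTKV}). Patients without any
  measured follow-up HtTKV are excluded.
- **Model 2 (time-varying)**: the visit's concurrent HtTKV is substituted
  into the refit log₂HtTKV term; visits with missing HtTKV are excluded
  (or imputed first).

Frozen terms always keep their original baseline-based values; in
particular the frozen `t × log₂HtTKV` interaction is still evaluated at the
baseline volume. Only when the interaction itself is refit
(`with_interaction=True`) does it see the time-varying value — otherwise a
coefficient estimated against a baseline covariate would be applied to a
systematically larger, grown covariate, which is a recalibration error
rather than an update.

Updated models are scored by patient-level k-fold cross-validation
(default k = 5, all visits of a patient share a fold, fold sizes within
one): the update is refit on k−1 folds and scored on the held-out fold,
metrics pooled over all held-out predictions.

## Metrics

- Bias = mean(observed − predicted); 95% limits of agreement =
  bias ± 1.96·SD of the differences (n−1 denominator; 1.96 literally, not
  a t-quantile).
- P30 = percentage of predictions within 30% of the observed value,
  boundary inclusive.
- R²: both `1 − SSE/SST` and squared Pearson correlation are always
  carried (they coincide only for unbiased linear predictions; published
  validation reports are often ambiguous about which was used, and the two
  visibly disagree once predictions are biased). The headline variant is
  configurable and defaults to `1 − SSE/SST`.
- AIC = −2·loglik + 2·(fixed effects + 2 variance components), under ML.
  For a frozen model applied to new data the log-likelihood is the
  marginal Gaussian likelihood with per-patient covariance
  `σ_b² t t' + σ_e² I`. AIC and CRPS are reported only for models with a
  predictive distribution; the risk-class validation row carries neither.
- CRPS of a Normal(μ, σ) forecast uses the closed form
  `σ·[z(2Φ(z)−1) + 2φ(z) − 1/√π]`, `z = (y−μ)/σ`, with `|y−μ|` at σ = 0.
  `crps_sample` implements the empirical CRPS
  `mean|X−y| − ½·mean|X−X′|` over all ordered pairs via an O(n log n)
  sorted-prefix identity, serving as the Monte-Carlo oracle for the closed
  form.

## Multiple imputation

Missing follow-up HtTKV (and only that column) is imputed under a joint
multivariate-normal model of {log₂HtTKV, t, age, sex, observed eGFR,
baseline eGFR} — the outcome is deliberately included, as leaving it out
biases the imputed covariate–outcome association toward zero. The sampler
is classic data augmentation: draw (μ, Σ) from the normal–inverse-Wishart
posterior (Jeffreys prior) given the completed data, then draw the missing
values from their conditional normal. Defaults: m = 30 completed sets,
500 burn-in iterations, thinning interval 100 — unstated in typical
published analyses; chosen generously relative to the chain's very fast
mixing (a single column of ~3% missing values) and exposed in the API.
Imputation on the log₂ scale guarantees positive back-transformed volumes
and makes joint normality plausible. Scalar performance metrics are pooled
by the mean across imputations; coefficient sets by Rubin's rules
(between-imputation variance `B = Σ(q_i − q̄)²/(m−1)`, total
`T = W + (1+1/m)B`).

## The synthetic cohort generator

The generator is the package's study environment, not a fixture. The
**validation-style** default emulates a contemporary European ADPKD cohort:

| quantity | default | rationale |
|---|---|---|
| n | 214 patients | validation-sample scale |
| age | accept/reject toward N(34, 9.6²) on [19, 55] | median 34 (IQR 27–40) |
| eGFR₀ | truncated N(82, 18.5²), floor 30 | median 82 (IQR 70–95), eligibility > 30 |
| HtTKV₀ | log-normal, median 497 ml/m, log-SD 0.65 | median 497 (IQR 317–762) |
| visits | first at U(0.5, 1) y, then annual ± 0.15 y | second visit within 6–12 months, annual after |
| follow-up | per-patient U(0.42, 10.28) y | observed range, median ≈ 5 y |
| HtTKV noise | 5% CV, mean-corrected log-normal | MRI volumetry repeatability |
| eGFR noise | σ_e = 5, σ_b = 2 /yr | limits of agreement a few tens wide at 5 y |
| missing HtTKV | 3% MCAR on follow-up visits | stated missingness; MCAR is the simplest mechanism consistent with an MI analysis |

Kidney growth is exponential per patient. The hidden true rate is the
class-typical (birth-anchored) rate scaled by a **prospective growth bias**
of 2.3 with 25% log-normal scatter: growing exactly at the birth-anchored
rate would keep every patient on their class curve forever, whereas adult
cohorts progress — the factor is calibrated so that ~25% of patients move
to a more severe class over a median 5-year follow-up, matching the
transition behaviour such cohorts report. Regression to milder classes
arises only from measurement noise and lands near 1–2%.

eGFR observations come from the generating mixed model. The subject slope
`b_i` is optionally **coupled to the true growth rate**
(−30 ml/min/1.73 m² per year per unit rate deviation from the median):
biologically, faster-growing kidneys lose function faster, and this
coupling is what makes additional kidney-volume measurements genuinely
informative for the updated models. Setting the coupling to zero makes the
generator sample exactly from the declared mixed model (used by the
parameter-recovery tests).

The **development-style** config emulates the older population such models
are developed on (age ~N(44, 10²), eGFR₀ median 71, HtTKV₀ median 651
ml/m, follow-up to 11 y) and a generating truth whose HtTKV coefficients
differ modestly (−2.2 and −0.95 vs −2.0 and −0.9 for the main and
interaction terms): population and TKV-measurement-method differences make
an externally developed model slightly miscalibrated on the validation
population, in exactly the coefficient the update refits. This is the
mechanism behind the frozen model's positive bias and the updates'
systematic CRPS advantage in the end-to-end runs.

Creatinine is back-derived from eGFR by inverting the CKD-EPI 2009
creatinine equation (constants embedded explicitly; the race coefficient
is omitted — it is not describable from the available fields and is
irrelevant to the mechanisms under test). The generator parameterizes eGFR
directly; the derived creatinine is synthetic-only.

All randomness flows from one master seed through `SeedSequence`-spawned
sub-streams (baselines, schedules, volumes, eGFR, missingness, rates), so
a config reproduces its cohort byte-for-byte, and the pipeline reproduces
its whole output bundle byte-for-byte from a master seed.

### What passing tests do and do not show

The generator reproduces the *structure* of a real cohort (eligibility,
visit cadence, marginal baseline distributions, exponential growth, linear
decline, MCAR missingness) but not its full complexity: no informative
dropout, no dialysis/death truncation, no genotype strata, no
non-linearity of decline near low eGFR, and MCAR rather than MAR/MNAR
missingness. Tests passing on this environment demonstrate that the
statistical machinery is correct and well-calibrated under its stated
assumptions — not that the specific published coefficient values transport
to any particular clinic.

## Numerical choices

- Mixed-model convergence: statsmodels defaults with `maxiter=500`; fits
  are deterministic (no stochastic initialization).
- Rank of the fixed-effect design is checked up front; a singular design
  (e.g. a single-sex cohort) raises an informative error rather than a
  degenerate fit.
- The empirical-CRPS pairwise term includes all n² ordered pairs
  (self-pairs contribute zero), matching the plain mean-over-pairs
  definition.
- Degenerate inputs: empty cohort generation returns an empty cohort;
  a transition summary with nobody assessable reports NaN percentages;
  `crps_normal` at σ = 0 returns `|y − μ|` exactly.
- Problem sizes in the test suite (n = 500 × 20 seeds for recovery,
  n = 376/214 × 20 replicates for the frozen-vs-updated comparison,
  10⁶ draws per CRPS grid point) were chosen to keep Monte-Carlo error
  comfortably inside each assertion's tolerance.

## Known limitations

- Model 1's "second measurement" uses the earliest measured follow-up
  visit, whatever its timing; a 6–12-month window restriction is not
  enforced.
- The AIC of a frozen model on new data counts the frozen coefficients as
  parameters, which is a convention (they were not estimated on these
  data); AIC comparisons are therefore only meaningful between models
  evaluated the same way.
- MI assumes joint normality on the transformed scale; heavy-tailed or
  multimodal volume distributions would call for predictive-mean matching
  or FCS, which are out of scope.
- The generator's eGFR floor (1 ml/min/1.73 m²) technically truncates the
  Gaussian residual; at default noise levels it touches a handful of
  visits per thousand and is ignorable.
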