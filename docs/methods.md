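# Methods

## The oxidative balance score

The OBS is the sum of 20 component scores, each in {0, 1, 2}, so the total
lies in [0, 40].  Sixteen dietary components (fiber, carotene, riboflavin,
niacin, vitamin B6, total folate, vitamin B12, vitamin C, vitamin E, calcium,
magnesium, zinc, copper, selenium as antioxidants; total fat and iron as
pro-oxidants) are scored against sex-specific tertile cutoffs of daily
intake.  Antioxidants score 0/1/2 from the lowest to the highest tertile;
pro-oxidants the reverse.  Four lifestyle components are categorical:
physical activity (low/moderate/high → 0/1/2, antioxidant), alcohol
(heavy/non-heavy/none → 0/1/2, with heavy meaning ≥ 30 g/d for men and
≥ 15 g/d for women, boundary inclusive), BMI category
(obese ≥ 30 / overweight 25.0–29.9 / normal < 25 → 0/1/2) and smoking
(current/former/never → 0/1/2).

Cutoff conventions:

* **Tertile boundaries.** A value ties into the *lower* group:
  score bands are `≤ c1`, `(c1, c2]`, `> c2`.  This is the literal reading
  of the published cutoff table and makes the scoring a left-closed step
  function.
* **Data-driven cutoffs** use the type-1 (inverted-CDF) empirical quantile —
  the smallest observed value whose empirical CDF reaches 1/3 or 2/3 — so on
  values 1..9 the cutoffs are (3, 6) and each tertile holds n/3 up to ties.
  Degenerate data (c1 = c2) raise rather than silently producing a
  two-band component.
* **Underweight BMI** (< 18.5) is absent from the published category table.
  Default: scored as "normal" (2 points), because the pro-oxidant being
  scored is adiposity; configurable via `builtin_table(underweight_score=...)`.
* **Missing components** contribute 0 points under the default policy and
  are reported through `n_complete`; a prorated policy
  (total × 20 / n_complete) is selectable.  Participants passing the
  completeness filter can still lack up to 3 components, so the default
  slightly shrinks their totals — transparent, and the convention most OBS
  analyses use.

lnOBS = ln(OBS) is the modelled exposure; it is defined only for OBS ≥ 1 and
is NaN otherwise (flagged, never silently imputed).

## Cohort preparation

The exclusion chain removes, sequentially and with each record counted at
its first failing stage only: age < 18 (or missing), fewer than 17 of the 20
component inputs present, missing serum uric acid, missing any required
covariate.  The stagewise report conserves counts by construction.

Hyperuricemia: SUA ≥ 416 µmol/L (men) or ≥ 357 µmol/L (women), boundary
inclusive; the mg/dL → µmol/L helper uses 59.48 µmol/L per mg/dL rounded to
integer µmol/L (7 → 416, 6 → 357).

Quartiles of the (integer-valued, heavily tied) OBS use a rank-based rule:
the k-th boundary is the largest observed value whose cumulative count is at
most k·n/4.  Ties at a boundary fall into the lower quartile, so quartiles
form contiguous integer ranges, and the rule is invariant under any strictly
increasing transform — labels computed on OBS and on lnOBS agree
elementwise.  How ties were resolved in the source analyses is not stated
anywhere; this rule is the one that reproduces contiguous printed integer
ranges and is documented as an inference.

## Association models

* Model 1: unadjusted.  Model 2: age, sex, race/ethnicity.  Model 3: Model 2
  plus BMI, education, smoking, drinking, diabetes, hypertension,
  hyperlipidemia.  Reference levels: sex = female, race = Non-Hispanic
  White, education = lowest, quartile = Q1.
* SUA is fitted by ordinary (or weight-scaled) least squares; β is the SUA
  change in µmol/L per unit lnOBS, with large-sample Wald 95% CIs.
  Hyperuricemia is fitted by maximum-likelihood logistic regression
  (GLM-binomial); ORs are exponentiated coefficients with Wald CIs, which
  are symmetric on the log scale.
* Crude quartile ORs have the closed form OR = ad/bc with
  SE(log OR) = √(Σ 1/cell); a zero cell raises rather than being silently
  continuity-corrected.  The unadjusted categorical logistic fit must agree
  with this closed form to ≤ 1e-6 relative — a dual-route check kept in both
  the tests and the acceptance script.
* Fits are **unweighted by default**.  The published crude quartile ORs are
  exactly what the unweighted counts give, so the default reproduces the
  printed numbers; a frequency-weight column is accepted for exploration,
  but design-based (complex-survey) variance estimation is out of scope and
  weighted CIs should not be read as survey-correct.
* Subgroup analysis refits the spec within each stratum (covariates
  redundant with the stratifier removed) and tests effect modification by a
  Wald test of the exposure × stratifier product term in the pooled model
  (likelihood-ratio alternative via `test='lrt'`).  Age groups default to
  <60/≥60 years and BMI groups to <25/25–30/≥30 kg/m² — conventional
  cutpoints, configurable, flagged as inferred rather than prescribed.
  Strata smaller than `min_n` (default 50) or with a single outcome class
  are skipped with a warning and recorded.
* Singular designs raise `SingularDesignError` naming the collinear columns
  (detected by SVD rank); separation or non-convergence in logistic fits
  raises `SeparationError` with a diagnostic.

## The synthetic cohort generator

The generator emulates the *structure* of a US adult survey cohort, not any
real sample:

* **Dietary intakes** are log-normal per sex.  Defaults solve (mu, sigma)
  from the published sex-specific tertile cutoffs: tertile boundaries of
  LogNormal(mu, sigma) sit at exp(mu ± z·sigma) with z = Φ⁻¹(2/3) ≈ 0.4307,
  giving mu = (ln c1 + ln c2)/2 and sigma = (ln c2 − ln c1)/(2z).  Large
  simulated samples therefore reproduce the published cutoffs to within
  sampling error (tested at ±10%).
* **Correlation.** Real nutrient intakes are strongly positively correlated
  (diet quality), which is what gives the OBS its wide dispersion.  A shared
  standard-normal latent factor enters every log intake with loading
  λ = 0.74 (marginals unchanged).  λ was calibrated once so the simulated
  OBS dispersion matches the reported 19.96 ± 7.17 (uncorrelated components
  would give SD ≈ 3.7), and frozen.
* **Lifestyle and covariates** are categorical draws with probabilities set
  near the published baseline marginals (physical activity 30/40/30,
  smoking never/former/current 56/22/22, BMI categories 1.5/26.5/32/40,
  non-drinkers 34%, hypertension 36%, diabetes 14%, hyperlipidemia 35%,
  five-level race and education distributions; PIR ~ Gamma with mean 2.53,
  SD 1.63).  Binary smoking/drinking covariates are derived consistently
  (ever-smoker = former ∪ current; drinker = alcohol > 0).
* **Outcome.** SUA = intercept(sex) + obs_effect(sex)·lnOBS + N(0, sd(sex)),
  with lnOBS computed from data-driven sex-stratified tertiles of the
  complete (pre-missingness) intakes — so the true conditional slope given
  sex equals `obs_effect` (default −14 µmol/L per unit lnOBS, negative as in
  the motivating analyses; a per-sex mapping enables interaction studies).
  Intercepts (411 male, 338 female) and noise SD (60) were chosen once so
  hyperuricemia prevalence lands near the reported 19.3% overall
  (≈ 22/16% by sex).  Missingness is then applied independently per dietary
  component (default 2% per cell).

What the generator does **not** emulate: survey design (strata, PSUs,
oversampling, weights), dietary measurement error and recall bias,
nutrient-specific correlation structure beyond the single diet-quality
factor, heavy-tailed SUA noise, and any real confounding between covariates
and diet (covariates are drawn independently of intakes).  Passing
parameter-recovery tests therefore shows the estimators are correct under
the stated generative model — not that the substantive epidemiological
estimates would replicate on real microdata, which is explicitly out of
scope here.

## Problem sizes and numerical choices

Simulation-based validation uses n = 5000 with 100 replicates for slope
recovery (coverage ≥ 90/100 required), n = 6000 with 30 seeds for
interaction power under sex-specific slopes −20/−8 (≥ 80% required), and
n = 4000 with 60 seeds for null calibration of the interaction p-value
(Kolmogorov–Smirnov uniformity at α = 0.01).  These sizes give stable
checks while keeping the full suite under half a minute.

Other numerics: quantiles are type-1 (inverted CDF) everywhere tertiles or
quartiles are derived; rank-deficiency tolerance follows the standard
SVD-based machine-epsilon rule; logistic convergence is declared failed if
statsmodels reports non-convergence or any |coefficient| exceeds 30 (a
practical separation screen); percentages and estimates print at two
decimals, p-values at four with "<0.0001" below 1e-4.

## Known limitations

* Adjusted (Model 2/3) coefficients from published survey analyses cannot be
  reproduced numerically without the underlying microdata; only their
  schema, sign and dose–response behaviour are validated, on synthetic data.
* The completeness filter counts the 20 component *inputs*; lifestyle inputs
  are rarely missing in practice, so the filter mostly bites on diet.
* The prorated missing-data policy rescales the total but not the quartile
  boundaries, which are always derived from the totals actually produced.
* Frequency weights affect point estimates only in the intended way; their
  variance estimates are model-based, not design-based.
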