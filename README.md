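# oxbalance

Oxidative balance score (OBS) construction and serum-uric-acid association
analysis for NHANES-like cohort tables.

## The problem

The oxidative balance score is a composite exposure used in nutritional
epidemiology to summarise a person's overall antioxidant-versus-pro-oxidant
profile.  Twenty components — 16 dietary nutrients and 4 lifestyle factors,
of which 15 are antioxidants and 5 pro-oxidants — each contribute 0–2 points.
Dietary components are scored against sex-specific tertile cutoffs
(antioxidants 0/1/2 from the lowest to highest tertile, pro-oxidants the
reverse); lifestyle components are scored from categories (physical activity
low/moderate/high; alcohol heavy/non-heavy/none with heavy meaning ≥30 g/d
for men and ≥15 g/d for women; BMI obese/overweight/normal; smoking
current/former/never).  The total OBS ∈ [0, 40]; higher means a more
antioxidant-dominated profile.

This package implements the full analysis pipeline relating OBS to serum
uric acid (SUA, µmol/L) and hyperuricemia (SUA ≥ 416 µmol/L in men,
≥ 357 µmol/L in women, i.e. 7 and 6 mg/dL):

* **`oxbalance.simulate`** — a synthetic NHANES-like cohort generator with a
  known lnOBS → SUA effect, so every downstream stage is testable without
  any data download;
* **`oxbalance.scoring`** — the 20-component scoring engine (`OBSScorer`),
  with fixed published cutoffs or data-driven sex-stratified tertiles;
* **`oxbalance.pipeline`** — the sequential complete-case exclusion chain
  (age ≥ 18, ≥ 17 of 20 components, SUA present, covariates present),
  hyperuricemia classification, and rank-based OBS quartiles
  (`QuartileBinner`; labels are invariant under the log transform);
* **`oxbalance.association`** — Model 1/2/3 covariate ladders for linear
  (β, µmol/L per unit lnOBS) and logistic (OR) fits of continuous or
  quartile lnOBS, closed-form crude quartile odds ratios
  OR = ad/bc with log-scale Wald CIs, and subgroup analysis with an
  exposure × stratifier interaction test;
* **`oxbalance.reporting`** — baseline-characteristics tables
  ("count (percent%)", "mean ± SD", t/ANOVA and chi-square p-values),
  association tables ("estimate (ci_low, ci_high) p") and forest-plot data.

Scorers, binners and association models follow the scikit-learn estimator
protocol (`fit`/`transform`, `get_params`, trailing-underscore fitted
attributes) and compose with sklearn pipelines.

## Worked example

```python
from oxbalance import (CohortConfig, generate_cohort, OBSScorer, apply_exclusions,
                       classify_hyperuricemia, assign_quartiles, ModelSpec,
                       fit_linear, fit_logistic, association_table)

cfg = CohortConfig(n_participants=10000, seed=42)   # true slope -14 µmol/L per lnOBS
cohort = generate_cohort(cfg)
scored = OBSScorer(cutoffs="derive").fit(cohort).transform(cohort)
retained, report = apply_exclusions(scored)
retained["hyperuricemia"] = classify_hyperuricemia(retained["sua_umol_l"], retained["sex"])
labeled, bounds = assign_quartiles(retained)

beta = fit_linear(labeled, ModelSpec(model_id=2, outcome="sua"))
ors = fit_logistic(labeled, ModelSpec(model_id=1, outcome="hyperuricemia",
                                      exposure="lnobs_quartile"))
print(association_table(beta)[["term", "summary"]].to_string(index=False))
print(association_table(ors)[["term", "summary"]].to_string(index=False))
```

prints (seed 42):

```
quartile boundaries: (13.0, 19.0, 25.0)
mean OBS 20.09 ± 7.03, hyperuricemia prevalence 18.73%
  term                        summary
ln_obs -11.68 (-14.67, -8.69) <0.0001
term                   summary
  Q1                  1.0(ref)
  Q2  0.79 (0.69, 0.91) 0.0011
  Q3 0.71 (0.61, 0.82) <0.0001
  Q4 0.69 (0.60, 0.80) <0.0001
```

The age/sex/race-adjusted β of −11.68 (95% CI −14.67, −8.69) covers the
generator's true effect of −14 µmol/L per unit lnOBS; the quartile odds
ratios fall monotonically below 1, the dose–response pattern expected when a
higher antioxidant balance lowers uric acid.

The same pipeline is available from the shell:

```sh
oxbalance simulate --out cohort.csv --seed 42 --n 10000
oxbalance score    --in cohort.csv --table derive --out scored.csv
oxbalance filter   --in scored.csv --out retained.csv --report stages.csv
oxbalance analyze  --in retained.csv --outcome hyperuricemia --model 1 \
                   --exposure quartile --out ors.csv
oxbalance report   --in retained.csv --stratifier hyperuricemia --out baseline.csv
```

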