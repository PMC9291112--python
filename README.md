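# placebo-enrich

Study-level analysis of the placebo response in randomized controlled
trials (RCTs) for alcohol dependence, built around a severity-based
**enrichment strategy**: trials enrolling heavy drinkers who show no
"spontaneous improvement" before treatment start (the *high-severity*
population) exhibit a lower and less variable placebo abstinence rate than
trials in the *mild-severity* population, so selecting high-severity
patients increases assay sensitivity.

The package is aimed at meta-analysts and trialists working from an
extraction table of placebo arms (one CSV row per trial): sample size,
number of continuously abstinent patients (dropouts = failures), intended
treatment duration, and summary moments of baseline alcohol consumption and
pre-treatment abstinence duration.

## What it computes

**Severity allocation.** Each study is classified by two criteria:

1. *Drinking risk level (DRL).* If the placebo group's mean baseline
   consumption is lower than the WHO medium-DRL threshold (60 g pure
   alcohol/day for men, 40 g/day for women; sex-weighted for mixed groups)
   the study is low/medium DRL and is allocated to the mild-severity
   population outright.
2. *Pre-treatment abstinence.* Among high/very-high DRL studies, those
   conducted in "not early abstainers" (abstinent < 14 days before
   treatment) are high-severity; early-abstainer studies are mild-severity.
   Inclusion/exclusion criteria decide when they bound detoxification
   across 14 days; otherwise the reported mean decides (≤ 11 d: not early;
   ≥ 17 d: early; strictly between: excluded as unclassifiable).

**Continuous severity fraction.** Per study, the share of high-severity
patients is estimated as

    %high-severity = P(abstinence < 14 d) × P(consumption ≥ DRL threshold),

each tail probability computed from the reported mean/SD under a normal or
(moment-matched) lognormal assumption, with the two criteria assumed
independent. E.g. 80% not early abstainers × 70% H/VH DRL = 56%.

**Random-effects meta-regression.** The placebo abstinence rate `y_i`
(a proportion) is modelled as

    y_i = β₀ + β_d·duration_i + β_s·severity_i + u_i + e_i,
    u_i ~ N(0, τ²),   e_i ~ N(0, v_i),   v_i = p_i(1−p_i)/n_i,

with τ² estimated by REML (method-of-moments available), coefficients by
weighted GLS with weights `1/(v_i + τ²)`, t-referenced tests with
`k − p − 1` df (Knapp–Hartung option), residual heterogeneity
`I² = τ²/(τ² + s²)`, adjusted `R² = 1 − τ²_model/τ²_null`, and predicted
abstinence rates with 95% CIs per population and month.

**Synthetic study tables.** A generator draws study collections from this
exact regime (class-conditional moment profiles, durations 1–12 months,
placebo arms of 8–392 patients, additive heterogeneity τ² = 0.007, binomial
sampling) together with a truth table, so allocation accuracy, estimator
bias, CI coverage, and p-value calibration are all testable end to end.

## Worked example

```
$ placebo-enrich simulate --seed 7 -o studies.csv --truth truth.csv
wrote 19 synthetic studies to studies.csv
$ placebo-enrich allocate studies.csv -o alloc.csv
$ placebo-enrich fit studies.csv --covariates duration,severity -o fit.json
```

The fitted model (k = 19 studies):

```
intercept    +0.3871  p=0.003
duration     -0.0143  p=0.313
severity     -0.2022  p=0.020
tau2=0.0073  I2=0.92  adjR2=0.33  k=19
```

Read: at a fixed treatment duration, a high-severity trial's placebo
abstinence rate is about 20 points lower than a mild-severity trial's
(the generating value is −0.1987); each extra month of treatment lowers it
by about 1.4 points in this draw; 92% of the residual between-study
variability is true heterogeneity (τ² ≈ 0.007 on the proportion² scale);
and the two covariates explain 33% of the between-study variance relative
to the intercept-only model. The full suite (descriptive table, normal /
lognormal / extended-sample sensitivity models, secondary adjustments, and
the prediction grid with plot data) is produced by
`placebo-enrich report studies.csv -o report/`.

## Layout

- `placebo_enrich.study_data` — record model, CSV I/O, unit normalization,
  country-specific standard-drink conversion.
- `placebo_enrich.severity_allocation` — the allocation decision tree.
- `placebo_enrich.severity_fraction` — normal/lognormal tail fractions and
  the independence product.
- `placebo_enrich.meta_regression` — REML/MoM τ², weighted GLS, I²,
  adjusted R², predictions (written from scratch; see `docs/methods.md`).
- `placebo_enrich.synthetic_data` — the generator and truth tables.
- `placebo_enrich.pipeline_report` — analysis suites and CSV reports.
- `placebo_enrich.cli` — the `placebo-enrich` command.
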