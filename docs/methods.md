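# Methods

## The model

The unit of analysis is a trial's placebo arm. The outcome is the
continuous-abstinence rate `y_i ∈ [0, 1]` (dropouts counted as failures),
modelled on the raw proportion scale:

    y_i = x_i'β + u_i + e_i,   u_i ~ N(0, τ²),   e_i ~ N(0, v_i)

`x_i` is an intercept plus study covariates (treatment duration in months;
population severity as a 0/1 indicator or as the continuous % of
high-severity patients; optionally age, % male, baseline consumption, and
pre-treatment abstinence duration). `v_i` is the within-study sampling
variance, `τ²` the between-study variance. The proportion scale is
deliberate: coefficients read directly as differences in abstinence-rate
points (a severity effect of −0.20 means 20 points lower), at the price of
a model that is not variance-stabilized and can predict outside [0, 1];
confidence bounds below zero are reported as computed.

### Within-study variance

Default `v_i = p_i(1−p_i)/n_i` with `p_i = events/n_i`. When a study sits
on the boundary (0 or all events) the plain formula degenerates to zero and
infinite weight; the shrunk proportion `(events + ½)/(n + 1)` is
substituted first. User-supplied variances are accepted. A caveat worth
knowing: plug-in binomial weights are mildly outcome-correlated (low
observed rates ⇒ smaller `v̂` ⇒ larger weight), which biases the intercept
downward by a few tenths of a point in simulation; alternatives
(pooled-rate or fitted-rate variances) redistribute rather than remove the
effect under the generator's rate truncation, so the transparent textbook
default is kept.

### τ² estimation

REML is the default: the restricted negative log-likelihood
`½[Σ log(v_i+τ²) + log det(X'WX) + Q(τ²)]` is minimized over a bounded
interval by Brent search, then polished by Fisher scoring on the analytic
score `½(y'PPy − tr P)` with `P = W − WX(X'WX)⁻¹X'W`. The polish matters:
near the optimum the likelihood is flat to float precision, and the
gradient root is stable to summation order (study order permutation changes
no output beyond 1e−12). The method-of-moments alternative generalizes the
Q statistic to regression: `τ̂² = max(0, (Q − (k−p−1))/C)` with
`C = tr W − tr((X'WX)⁻¹X'W²X)` at fixed-effect weights `W = diag(1/v)`.

### Inference

Coefficients solve the weighted normal equations at `w_i = 1/(v_i + τ̂²)`;
their covariance is `(X'WX)⁻¹`, optionally inflated by the Knapp–Hartung
scale `max(1, Q_gen/(k−p−1))` (truncated so it never deflates). Tests are
two-sided against t with `k − p − 1` df by default — the safer reference
when k is around 19 — with a normal option. `I² = τ²/(τ² + s²)` uses the
typical within-study variance `s² = (k−p−1)Σw/((Σw)² − Σw²)`, `w = 1/v`,
which reduces to `v` itself for equal variances and no slopes. Adjusted
`R² = 1 − τ²_model/τ²_null` against the intercept-only model on the same
studies and same τ² method; it is negative when covariates inflate `τ̂²`,
and a `−∞` sentinel flags the degenerate `τ²_null = 0 < τ²_model` case.
Models need `k ≥ p + 2` studies; a just-identified design (`k = p + 1`) is
refused rather than fit exactly with zero residual df.

## Allocation rules and their edge cases

- DRL: "lower than the threshold" is strict — a group mean exactly at
  the threshold is high/very-high DRL.
- Mixed-sex threshold: the per-sex cutoffs (60/40 g/day) are combined as
  `pct_male·60 + (1−pct_male)·40`, the least-assuming interpolation for a
  single group mean; `male_60` and `female_40` policies are available and
  every report logs which policy produced it.
- Abstainer rule: criteria bounds take precedence (a protocol that admits
  only patients detoxified < 14 days settles the question regardless of the
  reported mean); the mean rule's cutoffs are inclusive at 11 and 17 days
  and the open interval (11, 17) is an exclusion zone — too close to the
  14-day split to call.
- Low/medium-DRL studies never reach the exclusion branch: they are
  mild-severity regardless of abstinence duration.

## Severity fractions

The % of high-severity patients multiplies two tail probabilities computed
from reported moments, assuming independence of the two criteria (no
copula; the dependence structure is unidentifiable from study-level
moments). The normal computation uses the moments as-is, including the
negative-duration mass a normal implies for short abstinence means — the
lognormal sensitivity exists precisely to probe that. The lognormal is
moment-matched (`σ² = ln(1 + sd²/mean²)`, `μ = ln mean − σ²/2`), so the
arithmetic mean and SD are preserved exactly; log-moment fitting would be
the alternative had patient-level data been available. Degenerate `sd = 0`
puts all mass at the mean, with threshold ties going to the at-or-above
side, mirroring the strict DRL rule. A zero abstinence mean under the
lognormal is mapped to "everyone not early" (the distribution degenerates
at 0, below any positive threshold).

## The synthetic generator

The generator emulates a collection of placebo arms in the regime the
analysis targets: default k = 19 with a 11:8 high:mild mix; true rates
`clip(β₀ + β_d·months + β_s·sev + u, 0.01, 0.99)` with β = (0.4438,
−0.0256, −0.1987) and `u ~ N(0, 0.007)`; abstinent counts are binomial.
Class-conditional profiles drive the observable summaries: high-severity
studies draw abstinence means in 1–11 days (center 5.7), durations from
{1…6} months (mean ≈ 3.2); mild-severity studies draw abstinence means in
17–60 days (center 28.3), durations from {3…12} (mean ≈ 6.9); both classes
are heavy-drinking at baseline (≈ 131 vs 155 g/day), so severity is driven
by the early-abstainer axis, as in the published trial landscape. Arm
sizes are lognormal-bodied integers clipped to [8, 392]. A configurable
`indeterminate_fraction` plants exclusion-zone studies (abstinence mean in
11.5–16.5 d, flagged in the truth table, severity indicator ½ in the
linear predictor). One `numpy` Generator seeded once drives all draws.

What the generator does **not** emulate: patient-level drinking
trajectories, informative dropout (only "dropout = failure" is baked into
the rates), publication bias, correlated covariate measurement error, or
dependence between the two severity criteria. Passing tests therefore
demonstrate internal consistency of the estimators under the stated model,
not robustness to those real-data features.

Two intentional properties of the regime deserve note. First, additive
normal heterogeneity on the proportion scale forces truncation of true
rates at [0.01, 0.99]; in the lowest-rate cell (high severity × 6 months,
linear predictor ≈ 0.09) the clip binds for ~16% of draws, so `E[y|x]`
exceeds the linear predictor there by ≈ 0.7 points. Simulation-calibration
work at large k will therefore see small but systematic coefficient biases
that are features of the truncated generating model, not estimator
defects; CI coverage is unaffected (≈ 0.94 across coefficients at
k = 200). Second, binomial sampling plus plug-in weights adds the
intercept bias discussed above.

## Reporting conventions

Descriptive quartiles use linear interpolation between order statistics
(numpy's default percentile rule), with IQR = Q3 − Q1 exactly; quantile
conventions matter only at the second decimal for tables this small. All
computation is in proportions; percent appears only in formatted output.
Exclusion-zone studies are carried in a dedicated report section and in
each fit's `excluded_ids`, never silently dropped. Secondary models are
complete-case with the per-model k reported, and any covariate reported in
fewer than 10 studies is refused outright rather than fit on sparse data.

## Reproducibility boundary

The coefficient tables of the original 19-study analysis this package is
designed for cannot be recomputed from public material: the per-study
extraction table is not published, only aggregate descriptives. The
package therefore ships property-based end-to-end checks instead —
estimator-vs-oracle equivalence (REML vs likelihood grid, GLS vs explicit
normal equations, hand-computed moment toys), parameter recovery and
coverage on 500 synthetic tables at k = 200, Kolmogorov–Smirnov uniformity
of the severity p-value under a null generator, and ≥ 95% allocation label
recovery — plus desk-checkable identities (the 56% worked example; the
16.8%/36.7% prediction identity linking slopes, intercept, and grid
cells). Problem sizes in the test suite (k ≤ 12 for the likelihood grid,
500 × k = 200 for recovery, 200 replicates for calibration) were chosen to
make Monte-Carlo error small relative to the tolerances they assert.
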