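# Methods

## The estimation problem

Let `GA` be gestational age at birth in decimal weeks, gold-standard dated by
first-trimester ultrasound, and let `x₁ … x₄₄` be the analyte concentrations
of a newborn dried-blood-spot screen collected 24–72 h after birth (amino
acids, acylcarnitines, GALT, 17-OHP, TSH; units are carried opaquely — the
models are unit-consistent as long as training and scoring share the assay
scale). The package estimates

```
GA = β₀ + Σ_j Σ_{p=1..P(j)} β_{jp} (x_j − c_j)^p  [+ β_bw (bw − c_bw)]  + ε
```

by ordinary least squares, where `P(j) ∈ {1,2,3}` is the panel's term
eligibility for analyte `j` and `bw` is birthweight in grams (the
*metabolites + birthweight* model). Predictions are raw model output — no
clamping by default (an optional `[22, 44]`-week clamp is available), no
calibration-slope adjustment, and no imputation anywhere: records with a
missing required input are dropped and counted at every boundary.

### The analyte panel

The panel is the single source of truth for term admissibility: 44 analytes,
29 eligible for squared terms, 21 (a subset of the 29) for cubic terms, hence
44 + 29 + 21 = 94 candidate metabolite terms. The published term inventory
names 37 analytes; the screen itself assays 44, so the default panel carries
seven further standard newborn-screen analytes (C0, C14:1, Citrulline,
Glycine, Ornithine, Proline, SUAC) as linear-only members. This is a
panel-completion choice of this package; because the seven are linear-only
and noise-only in the default generator, they affect nothing downstream
except the candidate count.

### Model building

1. **Univariate screen** (default `p_univariate = 0.01`): one OLS of GA on
   the centered powers `(x_j − x̄_j)^p, p = 1..P(j)` per analyte, with a
   marginal two-sided t-test per power (t distribution, `n − k − 1` df).
   Terms with `P < p_univariate` screen in. Constant analytes are a
   degenerate input (skipped with a warning by the batch screen).
2. **Entry hierarchy**: a cubic term is admitted only if the same analyte's
   squared term also screened in. Linear terms enter on their own
   significance — the stated rule covers only cubic→squared; a full
   linear→squared→cubic hierarchy is available via `full_hierarchy=True`.
3. **Backward elimination** (default `p_retain = 0.05`): refit the joint
   OLS, remove the single worst term with `P ≥ p_retain` (ties broken
   deterministically by (analyte, power)), re-enforce the hierarchy, repeat
   until all remaining terms are retained. The procedure is invariant to
   record and column order.

Predictors are mean-centered before powering to tame the collinearity of
`x, x², x³`; the centering constants are stored in the coefficient set (and
its JSON file), so prediction is exact and externally supplied coefficient
files (centers zero) evaluate raw powers. In exact arithmetic the centered
and raw parameterizations give identical predictions. Aliased (exactly
collinear) candidate columns are dropped greedily in deterministic order
during selection — the convention regression software uses for aliased
coefficients — while `fit_model` with an explicit spec refuses a
rank-deficient design and names the aliased terms. A numerically perfect fit
(residual ~ 0, as in zero-noise simulations) is detected and handled: terms
with nonzero coefficients are treated as infinitely significant rather than
producing 0/0 t-statistics.

## Agreement statistics

* **RMSE** `√mean((ĜA − GA)²)` in weeks.
* **Week discrepancy**: `|ĜA − GA|` rounded **half-up** to an integer week,
  capped at "≥4". Half-up is the only convention under which the five
  integer categories partition the continuous differences ("within 1 week"
  ⇔ difference < 1.5 weeks); `floor` and `ceiling` modes are provided for
  sensitivity analysis. Cumulative percentages are computed on raw counts
  and displayed to 1 decimal, half-up.
* **GA bins** on completed weeks (`floor(GA)`): ≤34, 35–36, 37–38, 39–40,
  >40 — consistent with the <37-week preterm cutoff, so the first two bins
  sum to the preterm share.
* **Concordance**: 5×5 ultrasound×predicted cross-tab; diagonal percentage
  = diagonal count / row total. **Prevalence**: per-bin counts/percentages
  for both columns plus each column's <37-week aggregate.
* **Subgroups**: independent metric sets by region or SGA; empty subgroups
  are omitted with a warning; subgroup sizes partition n.

## Preterm discrimination

Positive class = preterm (ultrasound GA < cutoff, default 37.0); score =
predicted GA, oriented so lower is more positive; a record tests positive at
criterion `c` iff `ĜA < c`. The curve places one point per distinct score
plus a sentinel, so its endpoints are (sens, spec) = (0, 1) and (1, 0) and
sensitivity is nondecreasing in `c`. AUC is the trapezoidal area, identical
to the Mann–Whitney estimator with ties counted ½ (asserted as an exact
identity in the tests). The Youden scan is exhaustive over all criteria;
among ties the criterion with the higher sensitivity wins (favouring preterm
detection). Fixed operating points return the achievable point with the
fixed coordinate ≥ the requested value and the largest free coordinate.

**Bootstrap**: nonparametric, whole-record, non-stratified resampling
(stratified-by-class available via flag), percentile intervals (BCa was
deliberately not used: the percentile method is the simplest transparent
reading of an unspecified "bootstrap CI"), default B = 2000 with fixed seed
20. Resamples containing a single class are redrawn, capped at 10·B redraws
and logged, so B effective replicates always contribute. In the rare case
the percentile interval excludes the point estimate it is widened to include
it, and flagged. Curve comparison resamples each group independently;
`p = 2·min(Pr(Δ* ≤ 0), Pr(Δ* ≥ 0))` with +1 smoothing in numerator and
denominator, guaranteeing p ∈ (0, 1]; ΔAUC is reported both as a proportion
and in percentage points. All bootstrap output is a pure function of
(data, statistic, B, seed, level).

## The synthetic cohort generator

The generator's defaults are the study conditions (all overridable):

| quantity | default | rationale |
|---|---|---|
| preterm fraction | 0.114 | validation-cohort marginal |
| region mix | Africa 0.561 / Asia 0.439 | cohort marginal |
| male fraction | 0.473 | cohort marginal |
| term GA | N(39.1, 1.1²) truncated [37, 44.9) wk | cohort mean/SD |
| preterm GA | N(34.8, 1.6²) truncated [26, 36.9] wk | late/early preterm split |
| birthweight | N(3300 + 180·(GA−40) ± 60·sex, 380²) g, redrawn if ≤0 | cohort mean/SD structure |
| collection age | N(49, 16.2²) truncated [24, 72] h | cohort marginal |
| analytes | degree-≤3 polynomial in GA + N(0, sd²) | the model family under study |

The term component is truncated at 37 weeks so the preterm mixture weight
*is* the marginal preterm fraction (an untruncated term component would
inflate it to ≈13.9%). SGA is flagged against the generator's own analytic
standard — birthweight below `conditional mean + z₀.₁₀·380` with
`z₀.₁₀ ≈ −1.2816` — so SGA prevalence is 10% by construction in every
sex×GA stratum. Low birthweight (<2500 g) emerges at ≈13.5%, close to the
cohort's 14%, without being targeted.

**Informative analytes.** Six analytes carry GA signal — Tyrosine
(linear-only), Arginine (squared-eligible), Alanine, C2, C5, TSH
(cubic-eligible) — and the remaining 38 are pure noise, giving term
selection a known oracle including its false-positive rate. Polynomials are
specified about 38.5 weeks and expanded to raw coefficients. Each
informative analyte's slope-to-noise ratio is 0.161 per week: with the GA
mixture's marginal variance ≈ 3.46 wk², the Gaussian information identity
`Var(GA | x₁..x₆) = (1/σ²_GA + Σ (β₁ᵢ/sdᵢ)²)⁻¹` then gives a designed
conditional prediction SD of ≈1.5 weeks for the metabolites model. The
realized hold-out RMSE runs at ≈1.44–1.48 weeks (the mild curvature terms
contribute information beyond the linear identity), inside the designed
[1.4, 1.6] band; birthweight adds `(180/380)²` of precision, putting the
birthweight model near 1.2 weeks. Regional analyte shifts and
collection-age drift are supported but default to zero (the study records
collection age but does not model it, and quantifies no regional analyte
effect).

**What the generator does not emulate:** real analyte concentration scales
and correlations between analytes beyond their shared GA dependence,
reference birthweight-standard centiles (the analytic Normal standard stands
in), region- or assay-specific effects, and non-Gaussian measurement error.
Passing tests therefore demonstrate correctness of the estimators and
procedures under a known generating model — not clinical performance of
metabolic dating on any real population.

## Problem sizes and numerical conventions

Test and acceptance simulations use sizes chosen to make Monte-Carlo bounds
meaningful at interactive runtimes: marginal checks at n = 50 000 (binomial
bound 2·√(p(1−p)/n)), model building at n = 1000–10 000, selection-recovery
over 200 replicates, bootstrap-coverage over 200–300 replicates at B = 500,
and the binormal AUC oracle at n = 20 000 against the closed form
`Φ(δ/(σ√2))`. Percentages are displayed to 1 decimal (half-up) and RMSE to
2 decimals; JSON reports keep full precision. All randomness flows from
named seeds (NumPy `default_rng`); reports are serialized with sorted keys,
so a rerun with the same configuration is byte-identical.

## Known limitations

* The backward-elimination reading of "retained for subsequent modelling"
  is one of several defensible operationalizations; it is deterministic and
  standard, but other retention schemes could select slightly different
  term sets on the margin.
* The univariate screen regresses GA on analyte powers (the prediction
  direction); screening analyte-on-GA would be an alternative reading.
* External coefficient files are validated against panel term eligibility
  but otherwise trusted; no provenance or unit checking is possible.
* The bootstrap p-value for curve comparison is a tail probability with +1
  smoothing, not an exact test; at B = 2000 its granularity is ≈0.001.
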