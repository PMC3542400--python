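# Methods

## Scope and flow

The package answers one question for a survey population with one or two
24-hour dietary recalls per person: what percentage has *usual* daily total
folic-acid intake above a cut-point, under current intake and under a
scenario where corn masa flour is fortified with folic acid. The flow is
generate/load → exclusions → scenario totals → usual-intake model →
design-based inference → stratified tables. This note records the model,
the defaults, and the design choices made where the design was open.

## Fortification scenario

A scenario is `(L, C)`: fortificant level *L* (µg folic acid per 100 g corn
masa flour; default 140) and a food-code set *C*. The corn-masa-flour grams
in a reported food are proxied by its non-wholegrain gram content *g*
(corn masa flour is a non-wholegrain by manufacture, and for most matched
foods the entire grain component is non-wholegrain), so one row adds
`g·L/100` µg. Totals are assembled per person-day as
`food + added + supplement`. Everything upstream of grams — grain-equivalent
database lookups, unit conversions — is out of scope; grams arrive as an
input column. The packaged food list is a synthetic stand-in of 103
invented FNDDS-style codes pairing with the synthetic generator; users
supply their own list via `FortificationScenario.from_files`.

## Supplements

Per-product 30-day reports are converted to a person-constant daily amount
`Σ dose × servings/day × days/30`. Treating supplemental intake as constant
ignores genuine day-to-day supplement variation; for infrequent users this
understates within-person variance and makes the total-intake distribution
bimodal. `fit_usual_intake` is fitted on totals with supplements included
(the order the analysis prescribes); the λ-grid then typically selects a
weaker-than-log transform (λ ≈ 0.15 on the default synthetic population),
which is expected, not a defect.

## Exclusion cascade

Rules run in a fixed order — pregnancy, recall quality (day 1 any cycle,
day 2 only where a day-2 recall exists), missing supplement information,
supplemental intake ≥ 93,000 µg/day — and each removed person is attributed
to the first applicable rule, so overlapping flags do not double-count. The
ledger reports the final-n ratio against both candidate denominators (total
sampled, and post-pregnancy), since "eligible sample" is ambiguous; on the
published counts the total-sampled ratio (81.8% → prints 82%) is the one
that matches.

## Usual-intake model

1. **Scale.** Intakes are divided by their weighted mean before
   transformation (a location/scale standardization that keeps the power
   family's curvature comparable across λ); a shift keeps arguments
   positive when zeros occur (shift = 10⁻⁴ of the mean minus the minimum).
2. **Transformation.** λ is selected from a grid (−1 … 1, step 0.05;
   0 = log) to minimize the magnitude of the weighted skewness of
   transformed day intakes; ties break toward the smallest |λ|. Skewness
   was chosen over a full normality statistic because the back-transform
   bias adjustment is second-order and symmetric-tail misfit is what
   distorts cut-point exceedance.
3. **Covariates.** Weighted least squares of transformed intake on
   day-of-week and interview-mode indicators; estimates are subtracted to
   re-center every day at the reference (weekday, in-person). Day-of-week
   uses 3 levels by default (weekday / Friday / weekend; `dow_levels="full7"`
   gives 7) — weekend eating is the dominant signal and 3 levels cost fewer
   degrees of freedom in small strata.
4. **Variance components.** σ²_w = 2 × weighted mean of squared
   half-differences over two-day persons — an unbiased moment estimator
   needing no distributional assumption. Because only the two-day cycles
   contribute, the estimate is automatically "borrowed" for one-day-only
   cycles; `external_within_variance` lets a caller impose a value instead
   (a cohort with no two-day persons requires it). σ²_b = weighted variance
   of person means − σ²_w · mean(1/dᵢ), floored at 0.
5. **Usual values.** Each person mean is pulled toward the weighted grand
   mean by the square root of the reliability ratio
   fᵢ = σ²_b/(σ²_b + σ²_w/dᵢ): xᵢ = μ̂ + √fᵢ (z̄ᵢ − μ̂). The √fᵢ scaling makes
   the variance of usual values exactly σ²_b — the BLUP factor fᵢ itself
   would shrink the distribution's variance to fᵢσ²_b and understate tail
   percentages. fᵢ ∈ (0,1], and fᵢ = 1 when σ²_w = 0 (degenerate data
   round-trip exactly).
6. **Back-transform.** y = g(x) with a second-order bias adjustment
   `usual = g(x) + ½ g″(x) σ²_w`, matching the convention that usual intake
   is the long-run *average* of days (for the log case,
   E[e^{x+ε}] ≈ e^x(1+σ²_w/2)); results are clipped at 0.
7. **Exceedance.** The usual-intake distribution is the weighted empirical
   distribution of the per-person usual values; % above *c* is a weighted
   indicator mean. Numerical deconvolution of the full density was not
   implemented: the target quantity is a tail proportion, and the empirical
   representation is exact for it given the usual values. Estimates whose
   unweighted tail holds 1–11 persons are flagged not-estimable ("NE") —
   thin tails are unstable — while an empty tail is a clean 0 (so a
   subpopulation with no exceeders prints 0, not NE).

## Scenario pairing and monotonicity

Within a run, λ and the covariate coefficients are fitted once on the full
cohort's current-scenario totals and reused for every stratum; variance
components are re-estimated per stratum (falling back to cohort values when
a stratum has fewer than 10 two-day persons) and shared between the paired
current/modeled fits. Sharing the transform, coefficients and components
across the pair makes the comparison monotone by construction: raising
every day total raises every person mean, the grand mean, and hence every
usual value, so modeled exceedance ≥ current exceedance at every cut-point.
Independent per-scenario refits can flip individual cells through
transformation-selection noise; pinning the nuisance quantities to the
current fit removes that artifact and is the package's design choice. The
null scenario (L = 0 or empty food list) reproduces the current tables
bit-exactly.

## Design-based inference

Replicate weights are delete-one-group jackknife: persons are partitioned
at random into R groups (default R = 122); column r zeroes group r and
rescales the rest to conserve the weight total. The variance coefficient is
JK1, (R−1)/R, and t-tests use df = R−1; released-weight conventions vary
and neither choice is dictated, so both are documented here and fixed.
Replicate re-estimates of an exceedance reuse the full-sample model's usual
values and only re-weight the indicator — refitting the model per replicate
would mix model-selection noise into a design-variance estimate. Scenario
comparisons are paired on replicates by default (`paired=False` available),
which can only shrink the SE relative to independence.

## Synthetic generator

One seed drives every draw; identical configs give byte-identical tables.
What it emulates: lognormal usual food intake
(day totals `exp(b_i + σ_w ε) × dow × mode` with b_i ~ N(μ, σ²_b)); two
recall days except for a one-day fraction (that fraction is labelled cycle
2001–2002 and its day-2 quality flag is absent); a +10% weekend bump and a
−3% telephone effect (day 2 is telephone, as in practice); a supplement-user
subpopulation with person-constant doses; corn-masa consumption
concentrated in the Mexican American stratum; positive lognormal weights
with a full replicate set; planted exclusion-rule violations at low rates.

Defaults and why (the defaults *are* the study conditions for the
recovery tests): μ = 5.2 (geometric-mean food folic acid ≈ 180 µg/day, a
plausible post-fortification-era figure), σ_b = 0.5, σ_w = 0.6 (within >
between, as day-to-day nutrient variation typically exceeds between-person
variation; no survey-calibrated values exist for this quantity, so these
are stated as illustrative); supplement-user probability 0.342 and a
64.6-vs-~25% corn-masa consumer split by stratum (the survey-reported
figures); dose mix dominated by 400 µg with small 800/1000 µg shares, which
puts overall adult UL exceedance near 2% — the right order of magnitude;
one-day fraction 0.25 (one cycle of four); non-wholegrain grams lognormal
(meanlog 3.2, sdlog 0.6; mean ≈ 29 g, so default fortification adds ≈ 41 µg
to a consumer's day).

Ground truth: a person's true usual food intake is
`exp(b_i + σ²_w/2)` — the expected day intake at the reference covariate
level — plus the supplement constant, plus `g_i·L/100` under fortification.
Non-wholegrain grams are drawn once per consumer and held constant across
days so the fortified truth is exact rather than an expectation.

What it does **not** emulate, hence what passing tests do not show:
age- or sex-dependent intake levels (child exceedance of the lower
age-specific ULs is therefore much higher than a real survey would show,
though the qualitative ordering — young children and supplement users most
exposed — is preserved); stratified/clustered sampling design (weights are
independent of intake, so weighting is exercised but informative-design
effects are not); within-person supplement variation; correlated
food/supplement behaviour; real food-code structure.

## Problem sizes

Recovery tests use n = 5,000 persons per survey and 20 seeds for the
averaged recovery criteria; the generator calibration checks use one
n = 50,000 survey; pipeline tests run at n ≈ 1,000–1,500 with 30–40
replicates. These sizes put Monte-Carlo error comfortably inside the stated
tolerances (binomial/χ² standard errors are computed in the tests
themselves) while keeping the full suite fast.

## Known limitations

- The usual-intake model is a single-nutrient, daily-consumption model; it
  has no two-part structure for episodically consumed foods and no
  spline-assisted transformation, so it will not numerically match PC-SIDE
  or NCI-method output on real data, only agree in its target estimands.
- The empirical usual-value representation cannot resolve exceedance
  percentages finer than the weight of one person (~1/n); tails thinner
  than that are flagged NE rather than interpolated.
- Covariate adjustment is additive on the transformed scale; a
  multiplicative day-of-week effect on the raw scale is therefore removed
  only approximately when λ ≠ 0.
- The 82%/84% eligible-sample ambiguity and the BLUP-vs-√f scaling choice
  are documented above; both are fixed, deliberate choices.
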