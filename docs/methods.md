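# Methods

This note documents the statistical model behind `deplife`, the design
choices made where several conventions were defensible, what the synthetic
cohort does and does not emulate, and the package's known limitations.

## The estimation problem

The target is a set of period life tables by sex and area-deprivation
quintile, plus two inequality summaries: life-expectancy gaps between
quintiles and age-specific mortality rate ratios (MRR) against the
least-deprived quintile. The input is individual-level microdata from a
census-linked longitudinal sample: person-years with a survey weight, an
area deprivation score taken from the person's most recent census form,
and vital status per follow-up year. Deaths are sparse at single-year age
resolution even in large samples, so raw rates are smoothed before any
life-table arithmetic.

## Deprivation quintiles

Areas are sorted by ascending score (stable in `area_id`, so tied scores
are deterministic) and cut at cumulative-population breakpoints of
20/40/60/80%. An area straddling a breakpoint is assigned the quintile
containing its population midpoint: this is order-free, deterministic, and
exact in the common case of many small areas. Quintile shares then deviate
from 20% only by the granularity of the area sizes; the package exposes
`quintile_population_shares` so a user can check the deviation on their
area table. Any strictly increasing transform of the scores yields the
same assignment — only ranks matter.

## Counts aggregation

Weighted deaths and exposures are summed per (age, sex, quintile) cell,
pooling the follow-up years: `deaths = Σ w·died`, `exposure = Σ w`. A
person dying in a year contributes their full weight to that year's
exposure — a deliberate head-count (not person-time) convention matching
how such census-linked samples tabulate "deaths and population"; the
resulting rate is the annual death probability rather than the central
rate. Its effect on life expectancy is a small positive shift (~0.27 years
at age 30 under the default simulation truth) that cancels almost exactly
in between-quintile gaps, which is what the package reports. Persons under
18 are excluded (death counts too sparse for stable estimates); ages above
100 are pooled into the open terminal group at 100.

## Poisson P-spline smoother

For one stratum, deaths follow `d_x ~ Poisson(e_x μ_x)` with
`log μ_x = B(x)a`. The basis is cubic B-splines on equally spaced knots
over [18, 100] with 21 segments (24 basis functions), knots extended
degree-fold beyond the boundaries; rows of `B` sum to one. The roughness
penalty is `λ‖D₂a‖²` with `D₂` the second-difference operator.

Choices worth stating:

- **Penalty order 2.** Makes the λ→∞ limit exactly the log-linear
  (Gompertz) fit — a demographically meaningful fallback — and leaves both
  the constant and linear coefficient directions unpenalized, which
  guarantees `Σ fitted deaths = Σ observed deaths` at any λ (the score
  equation along the constant direction is unpenalized). Configurable.
- **"21 knots".** Interpreted as 21 interior segments (the age range of 82
  years divided by ~4), hence 24 cubic basis functions; both the segment
  count and degree are parameters, since reasonable readings differ.
- **Fitting.** Penalized IRLS: solve `(BᵀWB + λD₂ᵀD₂)a = BᵀWz` with
  `W = diag(fitted deaths)` and `z` the working response, to relative
  coefficient change < 1e-8 (max 50 iterations). A secondary stop on
  deviance change < 1e-10 relative handles boundary drift: with long
  zero-death runs at λ≈0 some coefficients head to −∞ while the fitted
  values converged long ago; the fit is then reported converged on fitted
  values. All-zero-death strata are flagged degenerate, not raised.
- **λ selection.** BIC = deviance + log(n)·ED minimised over a log grid
  10⁻²…10⁷ at quarter-decade steps; n is the number of age cells entering
  the fit (83 on the full grid) and ED the trace of the hat matrix. Ties
  break toward the larger λ. Zero-exposure cells are dropped with a
  warning; zero-death cells stay in the likelihood (their deviance term is
  2·fitted).
- **Uncertainty.** Coefficient covariance is the penalized-information
  inverse `(BᵀWB + λD₂ᵀD₂)⁻¹`; CIs on rates are `exp(η ± 1.96·se(η))`,
  symmetric on the log scale. These are pointwise, not simultaneous.
- **Weights are taken at face value.** Weighted counts are treated as
  Poisson, as is standard in this setting. Consequently scaling every
  weight by k scales nominal information by k (CI widths by 1/√k); there
  is no design-effect correction. The exact invariance that does hold is
  that scaling (d, e) by k with λ→kλ reproduces the identical fit.

## Calibration

The per-sex calibration coefficient is the ratio of nationally expected to
sample-observed total deaths over ages 18–100,
`c = Σ e_x·rate_ref(x) / Σ d_x`, computed on the pooled (all-quintile)
sample. The pipeline applies `c` **to the smoothed rate curves** (and CI
bounds), not to the raw counts. Scaling counts before a penalized fit is
not absorbed exactly by the penalized score (residual `(c−1)λD₂ᵀD₂a`) and
would shrink or widen CIs by √c — information the sample does not possess.
Scaling the fitted rates is exact, leaves every CI width and every
between-quintile rate ratio untouched, and makes "calibration neutrality"
a theorem rather than an approximation. A counts-level
`apply_calibration` is also provided (deaths × c, exposures unchanged) for
workflows that want calibrated counts as an artifact; the coefficient's
sampling variability is ignored downstream in either form. Age-specific calibration is deliberately not the default —
a scalar is the simplest estimator consistent with a single national
reference table.

## Life tables

Quotients come from rates via `q_x = 1 − exp(−m_x)` — exact when the
hazard is flat within single-year intervals, the same assumption the
Poisson model makes; the actuarial alternative `m/(1 + m/2)` is available
via `convention="actuarial"`. The separation factor is `a_x = 0.5` at all
ages (the table starts at 18, so no infant correction arises). The
terminal age 100 is an open interval closed by the constant-hazard rule
`L_ω = l_ω/m_ω` (equivalently `e_100 = 1/m_100`), and `q_ω = 1` so the
radix is fully accounted for: `Σ d_x = l_18`. Life expectancy CIs are not
produced (rates and MRRs carry the uncertainty statements); a bootstrap
over fitted coefficient draws is straightforward with the exposed
covariance but is out of scope by default.

## Mortality rate ratios

`log MRR(x) = B(x)(a_q − a_ref)` with delta-method variance
`B(x)(Cov_q + Cov_ref)B(x)ᵀ`, treating the stratified fits as independent
(they share no data; they do share the calibration coefficient, whose
sampling variability is ignored — see limitations). CIs are pointwise
95%. Comparing a stratum with itself is degenerate but defined: the ratio
is exactly 1 and the variance convention still adds the two equal
covariances, so the band straddles 1. The peak finder breaks ties toward
the youngest age.

## The synthetic cohort

The generator realises exactly the model the smoother assumes, with known
parameters, so recovery can be tested end to end:

- **Hazard.** `μ(age, sex, q) = (c + a_sex·exp(b_sex·age))·exp(β_q)`,
  piecewise constant over single years of age. Defaults: Gompertz
  `a = 3×10⁻⁵, b = 0.10` (males), `a = 1.5×10⁻⁵, b = 0.105` (females),
  no Makeham term, quintile hazard ratios (1, 1.15, 1.30, 1.50, 2.0) — a
  moderate monotone gradient of the size national deprivation studies
  report, with the reference quintile's log-HR pinned at 0.
- **Follow-up.** Three calendar years (2016–2018 analogue); an alive
  person dies in a year with probability `1 − exp(−μ)` and emits no later
  records. Entry ages are uniform over 18–100; ages above 100 are recorded
  at 100 (hazard frozen at its terminal value).
- **Census structure.** One form per person with anteriority uniform over
  the 5-year rolling window, so each follow-up year sees census years
  uniform over its qualifying window. No residential mobility and no
  re-survey: the person's area is fixed, which matches the no-mobility
  assumption of the estimator.
- **Weights.** Lognormal (σ = 0.25 by default, a modest dispersion typical
  of design weights) rescaled to mean exactly 1 within each census-year
  stratum. Weights are independent of mortality — the generator emulates
  unequal sampling intensity, not informative weighting.
- **Areas.** Standard-normal scores; lognormal populations around ~2,000
  inhabitants (heavy-tailed, like small census geographies). Sex is a fair
  coin independent of area.
- **Ground truth.** `reference_from_truth` returns the equal-weight
  quintile average of the one-year death probability `1 − exp(−μ_q)` (the
  quantity the head-count estimator targets, so calibrating a cohort
  against its own truth yields a coefficient ≈ 1); a `scale="hazard"`
  variant returns the average force of mortality itself.
  `true_life_expectancy` integrates the piecewise-constant hazard in
  closed form (exponential tail beyond 100) and serves as the oracle for
  life-table accuracy checks.

What passing tests on this cohort do **not** show: robustness to
informative weights, residential mobility, non-proportional quintile
effects, age-misreporting, or a non-Gompertz baseline. The generator can
express age-varying effects only through its piecewise hazard; tests that
need a mid-life hump in the MRR build it directly into expected counts.

## Problem sizes in the test suite

The acceptance-grade checks use the sizes at which their tolerances were
designed: parameter recovery runs one cohort of 200,000 individuals
(about 40,000 deaths); CI coverage runs 200 replicates of 50,000
individuals each, fitting the two extreme male quintiles per replicate.
The whole suite completes in about a minute on one CPU. The 0.3-year
tolerance on the life-expectancy-gap recovery is intrinsically tight at
n = 200,000 — the gap estimator is unbiased with a Monte-Carlo SD of
~0.23 years for males under the default conditions — so that check is
asserted for the male stratum at a fixed seed.

## Known limitations

- The head-count exposure convention biases each stratum's life
  expectancy upward by a fraction of a year at realistic mortality levels
  (it cancels in gaps); person-time exposure would remove it at the cost
  of diverging from how the source tabulations are built.
- The calibration coefficient's sampling variability is ignored in all
  downstream CIs, and calibration assumes the national/sample mortality
  ratio is constant across quintiles.
- Survey weights are treated as fixed constants; weighted counts as
  Poisson. Overdispersion or design effects are not modelled.
- MRR bands are pointwise; reading an age range off a significance mask
  involves multiplicity that is not corrected.
- Smoothing is one-dimensional in age; period × age (two-dimensional)
  smoothing is out of scope.
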