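# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Study system and data model

A flyway population of neck-collared geese winters across three discrete,
well-separated staging regions (Jutland, Friesland, Flanders).  The unit
of analysis is the *bird-winter*: the set of regions in which a bird was
sighted at least once between autumn arrival and spring departure.  Three
regions yield the seven nonempty subsets used as wintering strategies.
A *change event* is a bird with assigned strategies in two consecutive
seasons; the binary outcome is whether the region subsets differ.

Key conventions, chosen where the source material gives phenology rather
than dates:

* **Season boundary** July 1 — birds are on Arctic breeding grounds in
  midsummer, so no winter observation is ambiguous.  A season is labelled
  by its starting year (1991 = winter 1991/92).
* **Wintering window** Sep 20 – May 10, closed at both ends and
  configurable.  Observations outside it (e.g. Norwegian spring staging
  spillover) are excluded from strategy inference.
* **Single-sighting presence.** One in-window sighting establishes
  regional presence.  With ≈ 21 sightings per bird-winter, false regional
  absences are rare (< 5 %, measured by simulation) and false presences
  are controlled upstream by registry validation of collar codes.
* **Ringing-season exclusion.** Birds are caught in spring at the end of
  a winter; that incomplete winter is dropped.  The first study season
  (1990) is dropped for low sample size.
* **Missing ≠ empty.**  A bird-season with no in-window sightings is
  absent from the table; it never yields an empty region set, and no
  change event bridges the gap.
* **Age classes.** Known-age birds (ringed in their first winter) reach
  their third winter exactly two seasons after ringing — the first season
  in which a change event can be acknowledged.  Birds ringed as older are
  treated as adults throughout and never enter the 3rd-winter groups.
* **Pair deduplication** (breeding-status model only): the
  lexicographically smallest collar code among a pair's event-contributing
  birds is retained.

## Segmented trends

Per-strategy annual proportions are fitted untransformed (fidelity to how
such series are usually presented, despite boundedness) by continuous
piecewise-linear least squares using the hinge basis {1, x, (x−ψ)₊, …}.

* **Breakpoint search**: exhaustive coarse grid (one candidate per year)
  over all break combinations, then coordinate-wise refinement on a
  0.1-year grid; each segment must contain ≥ 2 observations.
* **Model size**: BIC over 0..max_breaks breaks, charging two parameters
  per break (slope change + location).  An RSS floor tied to the response
  variance makes the selector prefer fewer breaks on noiseless data.
* **Uncertainty**: residual bootstrap (default 500 replicates, seeded);
  replicates re-estimate breakpoints in a ±2-year local window around the
  point estimates.  Coverage of the 95 % interval was checked by
  simulation on constructed single-break series.
* **Davies test**: the Wald statistic for a slope-change term is evaluated
  at K = 10 evenly spaced interior candidate breakpoints; the p-value for
  the supremum uses the upcrossing bound p ≤ p_t(M) + V·k(M)/√(8π), with V
  the total variation of the statistic path.  Because the per-candidate
  statistics are t-distributed at these sample sizes, the kernel k(M) =
  (1 + M²/ν)^{−(ν−1)/2} replaces the large-sample exp(−M²/2); empirical
  size at n = 25 is ≈ 0.03–0.05 at α = 0.05 (the bound is conservative by
  construction).  The test is invariant to affine rescaling of x and y.
* **Periods**: breakpoints pooled across strategies are 1-D clustered with
  a 2-year gap threshold; cluster means are floored to season boundaries
  and the span is cut after each boundary year.

## Net exchange

Within a period (membership by the event's departure season), net(a→b) is
the difference of opposing change counts divided by all changes in the
period.  The matrix is antisymmetric with zero diagonal and the summed
|net| over unordered pairs is ≤ 1 (1 exactly when no pair has opposing
flows).  The display filter removes |net| strictly below 2.5 %; a flow at
exactly the threshold is kept.

## Switching GLMMs

All four faithfulness models are binomial-logit mixed models
fitted by maximizing a Laplace-approximated marginal likelihood:

  ℓ(β, θ) = Σ log f(y|η̂) − ½ û′D⁻¹û − ½ log|D| − ½ log|Z′WZ + D⁻¹|

with the random-effect mode û found by damped Newton iterations.  For the
crossed bird × year design the negative joint Hessian is an arrow matrix
(bird block diagonal, year block small), so each Newton solve and the
log-determinant use a Schur complement on the year block; cost is linear
in the number of birds.  Variance parameters are optimized on the log-SD
scale (bounded in [1e−4, 20]) with L-BFGS-B; an estimated SD at the lower
bound is reported as variance 0.  For single-factor models adaptive
Gauss–Hermite quadrature (probabilists' nodes recentred and rescaled at
the per-group Laplace mode) is available via `nagq`; on a balanced test
panel both routes agree with an independent reference mixed-model
implementation to ≈ 3 decimals in coefficients and variances.

Inference is Wald throughout (z = β̂/SE with SEs from the numerical
Hessian over β at the variance estimates — the usual mixed-model
convention), matching how such analyses report effects.  Probability-scale
effects are computed on the logit scale and back-transformed, giving
asymmetric CIs inside (0, 1).  Continuous covariates are centered
internally for conditioning; slopes are reported per original unit.

Degenerate inputs raise explicit errors: a constant response, or apparent
complete separation (|β̂| > 15) naming the offending covariate.  Year is
deliberately the only temporal fixed effect — population size is nearly
collinear with year over the study span and is never entered as a
covariate, so the year effect absorbs behavioural change and density
dependence jointly.

## Driver GLMs

Region-use responses are the summed proportions over the strategies
containing a region; "staying in Jutland" is the Jutland-only strategy
share.  Covariates are scaled to mean 0 and range 2 (x′ = (x − x̄) /
(range/2)), making estimates unit-free and comparable; the scaled
endpoints are ±1 only for series symmetric about their mean.  Land-use
models enter all of a region's crops jointly; harvest and temperature are
single-covariate models.  Quadratic terms (squares of scaled covariates,
re-scaled by the same rule) are screened one at a time at α = 0.05 and
retained only when significant; the screen is skipped (with a warning)
when residual degrees of freedom would fall below 2.  Administrative-unit
changes are handled by multiplying post-reform crop areas by
arable_old/arable_new — the direction that maps new-unit totals onto the
old-unit extent ("downscaling"); the opposite ratio would enlarge them.
Years with missing covariates are dropped listwise and logged.

## The synthetic-data generator

The generator is the package's stand-in for the undeposited field data and
defines the default study conditions:

| parameter | default | rationale |
|---|---|---|
| seasons | 26 (1990–2015) | study span |
| ringed / year | 160 | ≈ 4,100 birds total, matching the scheme's scale |
| annual survival | 0.83 | 5–6-year average lifespan |
| base change probability | 0.5 | mid-study annual change probability ≈ ½ |
| year trend (logit/yr) | 0.034 | ≈ 0.4 → ≈ 0.6 across 24 event years |
| SD(bird), SD(year) | 0.8, 0.3 | substantial individual heterogeneity |
| sex/age offsets (logit) | M3 +0.20, F3 −0.24, Mad +0.05, Fad −0.05 | group probabilities spanning ≈ 0.49–0.60 |
| pair-follow probability | 0.85 | males tend to adopt the mate's strategy |
| sightings / bird-winter | Poisson(21.3) | observed resighting intensity |

Each bird gets a ringing cohort, sex, age class, a Gaussian logit-scale
random intercept and (adults, within cohort) possibly a mate.  Strategies
evolve as a Markov chain: each season the bird changes with probability
logistic(intercept + trend·(year − mid) + bird RE + year RE + group
offset); on a change the destination is drawn from year-specific
attractiveness weights excluding the current strategy.  Default weights
interpolate anchor trajectories that mirror the study system's reported
dynamics (collapse of the Jutland–Friesland axis in the mid-1990s, peak
use of all three regions around 2000, strong short-stopping in Jutland
after 2007), so segmented trends and directional net exchange are
non-trivial on default output.  Sightings are Poisson-thinned uniform
dates in the window, uniformly allocated over the latent strategy's
regions; `perfect_detection` forces every latent region to be seen, making
downstream inference exact (the end-to-end identity used in testing).
Breeding status is i.i.d. Bernoulli per pair-season, shared by mates.

What the generator does *not* emulate: observer-effort variation between
winters, within-region spatial structure, non-independent brood success,
age-dependent survival, immigration, and misread collar codes.  Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to these real-data features.

Note that the bird-level random intercept alone induces positive
year-to-year autocorrelation of changing: the previous-change model
recovers a positive carryover coefficient on simulated data with SD(bird)
> 0 even though the generator has no explicit memory term — the same
mechanism offered for the field observation that changers change again.

## Problem sizes used in the checked experiments

Recovery and calibration batteries run at sizes chosen to give decisive
yet quick checks: year-trend recovery at ~700 birds × 12 seasons over 50
seeds; sex/age contrast at ~1,800 known-age birds over 50 seeds;
carryover at ~400 birds over 50 seeds; GLMM size at 200 null replicates;
Davies size at 1,000 null replicates (n = 25); driver size at 500 null
replicates.  Bootstrap coverage of breakpoint CIs is checked at 30 seeds
× 150 replicates.

## Known limitations

* Proportions are modelled by unweighted Gaussian least squares despite
  unequal annual sample sizes and the [0, 1] range.
* Laplace approximation can mildly underestimate random-effect variances
  for sparse binary panels; adaptive quadrature is available for
  single-factor models.
* The Davies bound is conservative; true size runs below nominal.
* Breakpoint bootstrap CIs are local (±2-year re-search window) and can
  undercover when the point estimate is far off.
* The period-derivation rule (pooling + 2-year gap clustering + floor
  rounding) is one defensible codification; alternatives could merge or
  split clusters differently on other data.
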