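# Methods

This note records the models the package implements, the assumptions and
defaults behind the synthetic-data generator, and the numerical and design
choices a maintainer would want to know.

## Study design

The analysis is ecological: every quantity is computed at the level of the
small area (an LSOA-style census unit of roughly 1,500 residents), and no
result is weighted by population size.  Counts of event finishes are
attributed to the finisher's area of residence; four finishes may be one
person finishing four events.  Inference about individuals is explicitly
out of scope.

## Access: distance to the nearest active event

For each area and calendar month, access is proxied by the geodesic
("direct linear") distance in km between the area centroid and the nearest
event **in operation on the 15th of that month**.  Conventions:

* *Activity rule.* Launch dates are inclusive, closure dates exclusive: an
  event launched on the 15th counts; one closed on the 15th does not.
* *Geodesic model.* Distances are solved on the WGS84 ellipsoid with a
  vectorised Vincenty inverse iteration (tolerance 1e-12 rad on the
  longitude difference, ≤ 200 iterations).  Against an independent
  Karney-style geodesic implementation the agreement is sub-metre on probe
  pairs spanning 0.01–800 km.  Vincenty's inverse does not converge for
  nearly antipodal pairs; such pairs raise rather than return an
  approximation (they cannot occur for any territory the package targets).
  A spherical haversine variant (R = 6371.0088 km) is available behind
  `method="haversine"` for cross-checks; it differs from the ellipsoidal
  distance by up to ~0.5 %.
* *Ties.* Two events at the same distance are resolved to the
  lexicographically smallest `event_id`, making panels reproducible.
* *Precision.* Distances are carried at full double precision; rounding is
  left to report time.

Absent closures, each area's distance series is non-increasing over time,
and inserting an event can never increase any cell — both are tested
invariants.

## Relative Index of Inequality

The RII summarises a socioeconomic gradient as the ratio of model-predicted
outcomes at the deprivation extremes.  Being regression-based it uses all
areas, not just the extreme ones.  Prediction points are the **observed**
minimum and maximum deprivation score in the analysis set (the score scale
runs from 0, least deprived, upward); a classical ridit-based variant was
considered and rejected as the package's primary definition because the
underlying study design predicts at actual extreme areas.

* *Distance RII* (per month): OLS of distance on score; RII =
  ŷ(score_min) / ŷ(score_max).  A nonpositive prediction at either extreme
  makes the ratio uninterpretable and raises an error — this can genuinely
  happen when the fitted gradient is steep relative to the mean distance.
  The ratio of linear predictions is invariant to multiplying all distances
  by a constant (both predictions scale), but not to adding one.
* *Participation RII* (per month): Poisson GLM with log link of that
  month's counts on score, with time-invariant `log(population)` as offset.
  For the log link, predict-and-divide collapses to
  `exp(slope · (score_min − score_max))`, an identity the tests check to
  1e-12.  Areas with zero population are excluded with a logged count.

## Poisson fitting

`fit_poisson_glm` is an IRLS maximiser of the Poisson log-likelihood with
offset.  Convergence requires the relative deviance change to fall below
`tol` (default 1e-8, `max_iter` 100) **and** the coefficient step to be
small; the second condition catches divergent likelihoods (e.g. all counts
zero, where the deviance underflows to zero while the intercept runs to
−∞) and flags them as non-converged instead of returning a spurious fit.
Standard errors come from the inverse Fisher information at the optimum;
AIC = 2k − 2ℓ.  Fits agree with statsmodels' GLM and with a direct
quasi-Newton maximisation of the same likelihood to ≤ 1e-6 in the tests.

For OLS, AIC counts the two regression coefficients (matching statsmodels'
convention); an exact fit reports infinite log-likelihood rather than
failing.

## Yearly determinants of participation

One model per calendar year: counts summed over the year's months per area,
regressed on deprivation score, ethnic density (%), population density and
the **within-year mean** of the monthly distances, with `log(population)`
offset.  Choices:

* *Density scaling.* Population density enters in thousands of
  persons/km² (`POP_DENSITY_SCALE = 1000`), so a coefficient of −0.008
  means −0.8 % participation per 1,000 persons/km².
* *Distance aggregation.* The within-year mean is the natural panel
  reduction; December-value or mid-year-value snapshots would be drop-in
  alternatives.  **Limitation:** in years when many events launch, the
  within-year mean misstates each area's effective exposure; because the
  roll-out concentrates in dense areas, this biases the (small) density
  coefficient upward and can flip its sign during the superlinear growth
  phase, while the deprivation, ethnic-density and distance coefficients
  remain essentially unbiased.  Once the registry is stable within a year
  the yearly model coincides with the monthly generative model and all
  coefficients are recovered within sampling error.
* *Quasi-Poisson.* Point estimates are identical to Poisson by
  construction; standard errors are multiplied by the square root of the
  Pearson dispersion estimate X²/(n − p).  With many all-zero areas (early
  years) the dispersion estimate is large and quasi-Poisson inference is
  very conservative.
* *Strata.* `urban` / `rural` re-fit on the subset given by the area's
  urban flag.  A stratum-year with zero finishers is non-estimable and is
  omitted with a logged message.

## Descriptives

Quintiles: areas ranked by deprivation score ascending (ties broken by
area id), split into five groups as equal as possible with any remainder
going to the lower (less deprived) quintiles; quintile 1 is least deprived.
Rates are **unweighted means of area-level rates** (1000 × count /
population), consistent with the unweighted ecological design; a pooled
variant (summed counts over summed population) is available behind
`pooled=True`.  Yearly rates use the year's summed counts.  Quantiles in
summary tables use linear interpolation between order statistics (the
"type-7" convention).

## Synthetic-data generator

The generator emulates the structure of the real panel so that every stage
is testable without a download.  What it reproduces, and how:

* *Deprivation marginal*: 100 × Beta(1.1, 3.97) — right-skewed with mean
  ≈ 21.7 and median ≈ 17.4, matching the reported score distribution.
* *Ethnic density marginal*: 100 × Beta(0.35, 2.2) — heavily right-skewed,
  mean ≈ 13.7 %.
* *Populations*: log-normal around 1,600 clipped to [900, 8,000].
* *Spatial structure*: a configurable fraction (default 0.8) of areas
  cluster around a handful of city centres; the rest scatter uniformly.
  Urban areas get log-normal densities around 3,600 persons/km², rural
  around 150.
* *Correlations* are induced by rank-mapping latent Gaussian scores through
  the fixed marginal quantile functions: deprivation is shifted upward in
  urban areas (`urban_imd_shift`, default 0.5 latent SD) and ethnic
  density loads on log density (`eth_density_coupling`, default 1.2).  The
  strengths are config knobs, not claims about any real territory.
* *Territory size*: the default bounding box spans roughly 135 × 135 km —
  deliberately smaller than a national territory — so that with the
  scaled-down registry the nearest-event distances match the reported
  scale (tens of km with the first events, ~5 km at 200 events).
* *Event roll-out*: a cumulative yearly schedule (default
  2, 6, 18, 50, 75, 100, 125, 150, 175, 200) growing superlinearly to year
  four and linearly after.  Launches fall on days 1–14 of a uniform month
  so the count of events active on 15 December of each year equals the
  schedule; the very first event opens with the panel so no month has an
  empty registry.  Host areas are drawn with probability proportional to
  `pop_density ** siting_bias_power` (default 2.0), the "urban-biased"
  siting that produces the falling distance-RII gradient for deprived
  areas.
* *Counts*: Poisson with mean
  `pop · exp(α + β_imd·imd + β_eth·eth + β_dens·dens/1000 + β_dist·dist) · s(month)`,
  where `s` is a cosine with July peak normalised to mean 1 over the year
  (default amplitude 0.35).  Default coefficients use the steady-state
  yearly determinants (β_imd = −0.035, β_eth = −0.009, β_dens = −0.008,
  β_dist = −0.088) with α the yearly constant −1.04 minus log 12 to put it
  on a monthly scale.  `dispersion` > 1 switches to a gamma-mixed Poisson
  (negative binomial) with variance = dispersion × mean, supporting the
  quasi-Poisson sensitivity analysis.

Every generator is a pure function of (config, seed).

*What the generator does not emulate:* real road networks or travel times,
within-area population distribution (centroids stand for areas), migration
or population change over time, event capacity constraints, weather and
cancellations, and any participation dynamics beyond the static log-linear
model (e.g. habit formation, word of mouth).  Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes, not that
the assumed structure captures any real territory.

## Problem sizes and determinism

The default synthetic study uses 3,000 areas over 120 months, a size at
which every stage — distance panel, 240 monthly GLM fits, 10 yearly
models — completes in seconds while leaving coefficient standard errors
small enough for meaningful recovery checks.  Calibration and recovery
tests use 20 fixed seeds at 2,000–3,000 areas.  `scripts/acceptance.py`
derives all randomness from its `--seed` argument and is byte-reproducible.

## Known limitations

* Geodesic distance is a proxy for access; travel time and perceived
  accessibility are outside the model.
* The RII carries no confidence interval (none is defined here), and the
  distance RII is undefined whenever a linear prediction at an extreme is
  nonpositive.
* The yearly determinant model inherits the within-year aggregation bias
  described above during rapid roll-out phases.
* Deprivation scores are treated as time-invariant; real composite indices
  are not comparable across revisions, so no interpolation is attempted.
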