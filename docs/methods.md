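# Methods

## The model

`chacoedge` estimates how forest structure — fractional tree cover (%),
fractional shrub cover (%), and aboveground biomass (AGB, t/ha) — varies with
distance to the nearest agricultural clearing, and how that relationship
depends on the post-deforestation land use and the age of the edge.

Each structure variable is modeled separately.  For sample point *i* with
nearest-plot land use `LC[i]`:

    FS_i ~ Normal(mu_i, sigma)
    mu_i = alpha_{LC[i]}
         + b_dist_{LC[i]} * d_i + b_age_{LC[i]} * a_i + b_distage_{LC[i]} * d_i * a_i
         + beta_temp * Temp_i + beta_precip * Precip_i + beta_dist_time * DistTime_i
         + beta_dist_home * DistHome_i + beta_dist_roads * DistRoads_i

where `d_i = z(log(Distance_i + 1))` and `a_i = z(log(Age_i + 1))` (the log
terms let the model fit the saturating shape of edge responses), the response
is `z(log(FS_i + 1))`, and the remaining covariates are z-scored untransformed.
The interaction column is the product of the two standardized columns, not
re-standardized.  All standardization constants are stored so curves can be
mapped back to natural units exactly.

The distance-only variant (`include_age=False`) drops the age main effect and
the interaction; it is the variant behind the headline per-land-use depths
and magnitudes, while the age-aware variant drives the metric-versus-age
trajectories.

Priors (all on the standardized scale): group-level means `~ Normal(0, 1)`;
group-level sds and the residual sd `~ half-Student-t(3, 0, 1)` — weakly
informative, lightly regularizing.  The four varying terms are modeled as
independent across terms: with only three group levels a correlation matrix
across varying effects is not identifiable, so none is attempted.

### Why a multilevel model

The three land uses are levels of a grouping factor, not arbitrary dummy
categories: partial pooling shrinks each land use's effect toward the shared
mean, which stabilizes the silvopasture level in particular (it typically has
the fewest nearby points) and bounds every group estimate between its
no-pooling and complete-pooling values — a property the test suite checks
directly.

## Sampling the posterior

MCMC settings: 2 chains × 2000 iterations, 500 warmup, so 2 × 1500 = 3000
retained draws.  Convergence is declared at rank-normalized split-R̂ < 1.01
for every parameter; ESS and divergence counts are reported alongside.

The sampler is written in the package (NUTS: multinomial trajectory sampling,
dual-averaging step size targeting 0.9 acceptance, expanding-window diagonal
mass adaptation, divergence detection at an energy error of 1000).  Because
the likelihood is Gaussian and linear in all location parameters, the sum of
squares is held as Gram matrices — every density evaluation is O(p²)
regardless of n — and, more importantly, all location parameters (the twelve
group coefficients, five fixed slopes, and four group means) are integrated
out analytically.  NUTS therefore explores only the scale parameters
(group-level sds and the residual sd; 3 or 5 dimensions), whose posterior has
none of the location-scale funnels that frustrate joint sampling of few-group
hierarchies, and each retained draw is completed with an exact draw of the
location block from its conjugate Gaussian conditional.  This scheme targets
the same joint posterior (the joint non-centered NUTS path is retained and a
test confirms the two agree within Monte-Carlo error) but converges
essentially perfectly: typical fits show R̂ ≤ 1.005 with zero divergences.

Chains run sequentially with seeds derived deterministically from the model
seed, so a fit is bit-reproducible.  Posterior-predictive checks draw
replicated response vectors from `Normal(mu(theta), sigma)` for random
posterior draws and compare the replicated-mean distribution with the
observed mean.

## Edge metrics

Conditional-effect curves are evaluated on a 1-m grid from 0 to 2000 m with
covariates at their sample means (standardized 0).  Each posterior draw's
linear predictor is back-transformed to natural units first (invert the
z-score, exponentiate, subtract the offset) and draws are averaged afterwards
— the posterior mean of the natural-unit curve, not the back-transform of the
posterior-mean predictor; with log-scale noise the two differ and the former
is the quantity a reader of a natural-unit plot expects.  The value *at* the
edge is the curve at d = 0, which the log(d+1) transform keeps finite.

* **Penetration depth**: the first sustained crossing of 90 % of the 2000-m
  value — the largest d\* such that FS(d) < 0.9·FS(2000) for all d ≤ d\*,
  plus one grid step; 0 if the curve already starts at or above the
  threshold.  "Sustained" guards against Monte-Carlo wiggle in
  nearly-flat curves.
* **Edge magnitude**: 100·(FS(2000) − FS(0))/FS(2000), signed — negative
  when the edge value exceeds the interior value (young silvopasture edges
  can show this).

Both metrics are invariant under positive rescaling of the curve.

## Footprint accounting

Every forest cell is attributed to its single nearest plot (no compounding of
multiple nearby edges — a deliberate simplification shared with the sampling
design).  A cell is *affected* if its distance is below the penetration depth
for the nearest plot's land use (land-use-specific buffering; a single-depth
variant is a config switch).  The relative deficit uses the fitted curve,
`r(d) = 1 − FS(d)/FS(2000)`, clipped to [0, 1]; an observed-shortfall variant
(`deficit_mode="observed"`) is available for sensitivity.  The potential
value of an affected cell is the mean observed value over *unaffected* forest
— the assumption being that unaffected forest represents what edge forest
would hold absent the edge.  Totals: affected/degraded areas (deficit ≥ 10 %)
in ha and as % of forest, absolute loss (potential × deficit × cell area),
and loss as % of the observed regional total.

## Geometry conventions

All coordinates are planar (projected) meters.  Distances are Euclidean from
a point (or cell center) to the nearest point of a plot polygon — exact for
the rectangular plots the generator uses, including corners — and one
convention serves sampling, the `Dist_Time` series, and the footprint
rasters.  `Dist_Time` integrates the annual nearest-cleared-plot distance
series by the rectangle rule (one rectangle per year, 1976–2020); years
before the first clearing are excluded rather than imputed.  Edge age is
`survey_year − year_cleared` in whole years (survey year 2020).  Rasters are
row-0-south grids written as ESRI ASCII (nodata −9999).

## The synthetic generator

The generator is the package's source of ground truth, not a fixture.  Its
default landscape is a 32 × 32 km window at 100-m cells — a deliberate
scale-down of the study region that preserves the study's sampling geometry
(3000 points, ≤ 2000 m from plots, ≥ 10 km from the boundary): 35
rectangular plots (0.5–2 km sides) cleared uniformly over 1976–2020, land
uses drawn as 40 % cropland / 40 % pasture / 20 % silvopasture (each level
guaranteed present), an east–west precipitation gradient (600→1000 mm) and a
south–north temperature gradient (18→24 °C) with cell-level Gaussian noise,
straight-line roads and random homesteads.

`model_matched` mode draws the standardized log response from exactly the
model's linear predictor plus `Normal(0, s)` noise (default s = 0.5),
using population-standardized predictors over forest cells within 2000 m of
a plot, then maps to natural units via a per-variable log-normal transform
(cover clipped to [0, 100]; clipping is vanishingly rare at the default
scales).  Default truth: positive distance slopes strongest for cropland
(0.35), moderate for pasture (0.20), near zero for silvopasture (0.02);
negative age main effects with positive distance-age interactions, so edge
effects deepen with age and silvopasture's early effect is slightly positive
before reversing.  The generator stores its transform in
`landscape.meta["generative_transform"]`; fitting with that transform frozen
makes recovery exactly well-posed (truth and estimand coincide), which is how
the recovery study is run.  Fitting with sample-estimated standardization —
the ordinary pipeline — recovers the same structure up to the response-scale
ratio.

`mechanistic` mode instead uses a saturating exponential profile
`FS(d) = FS_far·(1 − M_LC·(1 − e^(−lag·age))·e^(−d/λ_LC))` with
multiplicative log-normal noise — an off-model robustness path whose 90 %
point has a closed form used as an independent oracle.

What the generator does *not* emulate: remote-sensing error structure
(classification noise, resolution mixing), rivers/natural grasslands,
irregular plot shapes, spatial autocorrelation of the structural residuals,
and land-use transitions after clearing.  Passing tests therefore demonstrate
the correctness and calibration of the estimation machinery under the stated
generative conditions, not the ecological validity of any particular real-world
estimate.

## Problem sizes and numerical choices

The recovery study runs 20 replicates at the full design size (n = 3000,
σ = 0.5, study MCMC settings), checking ≥ 17/20 credible-interval coverage
per varying slope and distance-slope bias < 0.1; unit tests use a 6 × 6 km
landscape with a few hundred points and shortened chains.  The acceptance
script runs one full pipeline pass plus a five-replicate recovery.
Tolerances: density-oracle agreement 1e-8; generator-versus-oracle agreement
1e-9 on the log scale; standardization round-trips 1e-10 relative.
Tie-breaks: nearest-plot ties resolve to the lowest plot id; sampled cells
are sorted by cell index so the point table is independent of draw order.
Degenerate inputs raise: zero-variance design columns, missing group levels,
empty eligible cell sets, a survey year preceding all clearings, and
non-positive 2000-m reference values are all explicit errors, not silent
results.

## Known limitations

Single nearest-edge attribution understates compound edge effects in highly
fragmented areas; the potential-biomass estimator is a global unaffected-forest
mean (a climate-stratified potential would be a natural refinement); the
group-level effects are independent across terms by design; and the sampler's
collapsed scheme relies on the Gaussian-linear structure — a non-Gaussian
likelihood would require the joint path.
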