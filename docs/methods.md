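# Methods

This note documents the models, the synthetic-data assumptions, and the
numerical and design choices behind `energyscape`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The model chain

Four Gaussian/identity additive smooth regressions are fit independently
and then chained per day or per grid cell:

1. **Diel depth (models 1a/1b).** Mean day and night depths of tagged fish
   regressed on upper-200 m mean temperature, moon illuminated fraction and
   the depth of the 3.5 ml L⁻¹ dissolved-oxygen surface (a hypoxia-avoidance
   proxy for epipelagic tunas). Day and night are split on a local-solar
   clock derived from longitude, because the diel behavior is sun-relative,
   not UTC-relative.
2. **Metabolic cost (model 2).** Laboratory oxygen consumption
   (mg O₂ kg⁻¹ h⁻¹) as a tensor-product smooth of water temperature and
   swimming speed. Swimming speed is fixed at 2 BL s⁻¹ by day and 1 BL s⁻¹
   by night in gridded projections; along tag tracks the observed 3-D speed
   is used instead. Oxygen converts to energy at 13.59 J per mg O₂.
3. **Foraging (model 3).** Daily Heat Increment of Feeding (°C·hour)
   regressed on mesozooplankton biomass (a forage proxy), fish fork length
   and day length.
4. **Ingestion (model 4).** Meal energy (kJ) regressed on HIF, water
   temperature and the finfish percentage of the diet (fixed at 70% when
   unobserved). Predictions are floored at zero: a negative meal is a basis
   artifact, not biology.

Daily balance = ingested − 9.2% (specific dynamic action) − 27%
(excretion/egestion) − movement cost. The loss fractions act independently
and multiplicatively on ingested energy, so the balance is linear in
ingestion with slope 0.638 and in cost with slope −1. Somatic maintenance,
growth and maturation costs are not modelled; a positive balance is read as
energy available to those processes.

## The smooth-regression engine

Each univariate term is a cubic B-spline basis (knots at data quantiles)
with a second-order difference penalty; the temperature × speed interaction
is a row-wise Kronecker basis with one difference penalty per margin. The
raw spline basis spans the constant function, so each block is projected
onto the null space of its training column-sum vector (sum-to-zero
constraint) to keep the intercept identifiable. Smoothing parameters
minimize GCV over log₁₀λ (Nelder–Mead, λ clamped to 10^±8); fixed
user-supplied λ is also supported. The coefficient covariance is the usual
Bayesian posterior approximation σ²(XᵀX + S)⁻¹ with σ² from the residual
sum of squares over n − edf; posterior simulation draws from
N(coef, cov) with eigenvalue flooring if the covariance has drifted
slightly indefinite.

Prediction **clamps predictors to their training ranges by default**
everywhere the chain is applied to new environments. This is deliberate:
under future climates the fields leave the tagged-fish envelope, and basis
extrapolation of penalized splines is unbounded. Clamping events are
counted in the model metadata and logged. Outside the knots (clamp off),
basis functions extend linearly so values stay finite.

Optional monotone shape constraints are enforced by post-fit projection:
the fitted partial response is run through monotone (isotonic) regression
on a dense grid and the term's coefficients are re-solved against the
projected curve, keeping the coefficient representation (the covariance is
retained from the unconstrained fit — an approximation). No term is
constrained by default.

One test cross-checks the engine against an mgcv fit of the same problem
through Rscript; the engine itself has no R dependency.

## HIF extraction

The fasting baseline is a rolling 5th-percentile filter over a 6-h window,
smoothed by a 24-h centered moving mean. A rolling low quantile of a noisy
trace sits ≈ z₀.₀₅·σ below the true fasting level, so the noise scale is
estimated robustly from minute-to-minute differences (MAD/0.6745/√2) and
the offset added back; the correction is exactly zero on a noise-free
trace. Daily HIF is the trapezoid integral of max(body − baseline, 0) over
each local-solar 24-h period, in °C·hour; negative excess is truncated
before integration. Days with under 80% minute coverage are flagged, not
dropped. This baseline algorithm is the package's own encapsulated choice,
configurable and swappable.

## Synthetic data: what it emulates, what it does not

All inputs are emulated by seeded generators whose parameters are stored
with the output, so recovery tests read truth from the store and never from
the generated data:

- **Environmental fields** (monthly, cell-centered regular grid, default 1°
  over 20–60°N, 120°E–110°W): SST decreasing poleward with an
  August-peaking seasonal cycle; T200 = SST minus a positive,
  summer-stronger stratification offset; mesozooplankton increasing
  poleward and toward the eastern boundary with an early-summer peak; an
  O₂-3.5 surface shoaling in a fixed offshore band. The "future" period
  adds a warming offset (default +2 °C, varied a few tens of percent
  between sources) to SST/T200 and multiplies mesozooplankton by
  latitude-band factors (default 0.85 south of 40°N, 1.10 north) on the
  same noise draw, so a zero perturbation reproduces the historical fields
  exactly. Five labelled sources with small deterministic offsets stand in
  for a climate-model ensemble. Grid longitudes are stored monotonically in
  degrees east on [0, 360) because the domain crosses the antimeridian.
- **Tag records** (default 3 fish, ~3-month to 2-year deployments at 1-min
  resolution): a seeded random walk with seasonal east–west drift; body
  temperature = a slowly varying fasting baseline plus trapezoidal feeding
  pulses with exact closed-form areas (rectangles when the ramp is zero;
  pulse support is placed on the minute grid so trapezoid integration is
  exact); depth alternating deep-day/shallow-night on the solar clock,
  with the per-day day depth tied to the local O₂-3.5 depth when fields
  are supplied; linear growth between release and recapture. In the
  environment-driven feeding mode the daily pulse area is a stated linear
  function of local mesozooplankton and day length, which is what makes
  the foraging model recoverable.
- **Laboratory tables**: respirometry from
  mo2 = b₀ + b₁·speed² + b₂·exp(b₃·T) (defaults put routine MO₂ at
  100–400 mg O₂ kg⁻¹ h⁻¹); feeding trials from
  kJ = g₀·HIF·(1 + g₁(T − T₀))·(1 + g₂(pct − 70)/100) with g₀ = 400 kJ per
  °C·hour and deliberately mild modulation factors (a few percent across
  the sampled bands) so that the additive model structure used throughout
  the framework is a faithful description of the generated process.

The generators do not emulate ocean physics (fronts, eddies, interannual
variability), geolocation error structure, gaps or sensor drift in tag
records, or diet-composition variability. Passing tests therefore
demonstrate that the chain's plumbing, accounting and statistical machinery
are correct and recover known structure — not that the fitted responses
match real albacore physiology.

## Projection and habitat change

Gridded projection evaluates the chain per cell and month (mid-month date
for day length and moon phase), using a reference fish of 80 cm and 11 kg.
Ambient temperature at the predicted depth comes from a linear 0–200 m
profile with T(0) = SST and depth-mean equal to T200 — a documented
stand-in, since only those two temperature summaries are carried as
predictors. Diel cost weighting uses astronomical day length at the cell
latitude. Seasonal maps are means over DJF/MAM/JJA/SON months; the thermal
mask applies the inclusive 11–22 °C envelope to the seasonal-mean SST
(config-switchable to per-month masks).

Habitat change compares favorable-habitat area (cell areas
R²cosφ·Δλ·Δφ, R = 6371 km) and the area-weighted mean balance inside each
period's own mask, plus the change inside the intersection mask
("consistently favorable" habitat). Empty masks yield missing values, not
zeros. Ensemble summaries across sources report the mean, a t-based 95% CI
(suppressed for a single source), and a per-metric flag when sources
disagree on the direction of change.

Along tracks, horizontal distance is the haversine between consecutive
daily positions smoothed by a centered 7-day moving mean (edges use the
available window); vertical distance is half the summed absolute depth
changes (descents assumed nearly free); the 3-D distance is the scalar sum
of the two (a Euclidean composition is a one-line change; the scalar sum is
the conservative default). Track re-experience recomputes the daily balance
under two periods' fields with observed positions and speeds; swapping the
periods negates the difference exactly.

## Uncertainty propagation

Each model's posterior is sampled k times (default 10); the day and night
depth models share one slot and are drawn jointly, so the Cartesian product
has exactly four factors — 10⁴ chain realizations per climate source. The
product is enumerated lazily; full prediction sets are never materialized.
Per-cell 5th/95th percentile maps of balance change come with a
zero-overlap mask (where the interval contains zero, the projected change
is not distinguishable from none). Spread attribution uses a
one-factor-at-a-time design: the variance of a scalar summary when only one
slot varies, the climate-source slot entering through per-source summaries
at the point estimates. Proportions are of the summed one-at-a-time
variances — a ranking heuristic, not an exact ANOVA decomposition.

## Pipeline and determinism

Stages run in the order synth → hif → fit → track → project → uncertainty
(HIF extraction precedes fitting because the foraging model trains on the
extracted daily HIF). Every stage writes its outputs plus a manifest of
content hashes; a stage whose recorded outputs still exist is skipped, so
deleting an intermediate regenerates only it and everything downstream, and
a rerun with the same seed reproduces byte-identical artifacts. All
randomness derives from the single configured seed via named substreams.

## Problem sizes

Default test and pipeline sizes — 3 fish, 90–120-day deployments, a 2°
grid, 12 monthly fields, 5 synthetic climate sources, k = 3–5 posterior
draws for sweeps (k = 10 wherever the 10⁴ count itself is the quantity of
interest) — were chosen so the full suite and the acceptance script each
run in well under a minute on one CPU while leaving every statistical check
comfortably powered. Scaling up is a matter of configuration, not code.

## Known limitations

- The Gaussian/identity family is assumed for all four models; responses
  with hard zero bounds (depth, HIF, ingestion) are handled by clamping and
  flooring rather than by link functions.
- The constrained-fit covariance ignores the monotone projection.
- The linear temperature profile cannot represent mixed layers or
  thermocline sharpness; it is exact only in its two imposed moments.
- Nearest-cell sampling of fields introduces discretization noise at
  coarse resolutions; tracks outside the grid fall back to the nearest
  cell (counted and logged).
- The length–weight coefficients (W = a·L^b, b = 3.05, a set so that
  80 cm → 11.0 kg) are calibrated package defaults, not literature values;
  override them in `EnergeticsConstants` for real analyses.
- One-factor-at-a-time attribution ignores interactions between slots; the
  residual interaction spread is deliberately not forced into the reported
  proportions.
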