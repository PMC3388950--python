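# Methods

This note documents the models and procedures `modaccess` implements, the
assumptions behind them, and what the synthetic-data checks do and do not
establish.

## Facility intensity classification

Facility types are mapped to typical MET values (multiples of resting
energy expenditure) and graded by the standard cut-points: light < 3,
moderate 3–6 inclusive at both ends, vigorous > 6. The boundary
convention matters only at exactly 3 and 6 METs: 3.0 is moderate, 6.0 is
moderate, anything above 6 is vigorous.

Choices:

- **Lookup table.** A curated ~40-type CSV ships with the package
  (`modaccess/data/met_lookup.csv`). It is not a full activity
  compendium; it covers every type the synthetic generator emits and the
  canonical gradings (golf/bowling/cricket moderate; swimming pool,
  athletics track, shinty and Gaelic football vigorous; ballistics hall,
  croquet lawn and indoor small-bore rifle range light). Users supply
  their own CSV for real registers.
- **Hall fallback.** Types absent from the lookup whose names contain
  "hall", "community centre" or "pavilion" are assigned the midpoint of
  the moderate band (4.5 METs), reflecting the convention that such
  venues host badminton/table-tennis-grade activity. Other unknown types
  go to a rejects report rather than being dropped silently.
- **Deduplication** is an exact match on (type, coordinates). This is
  conservative; fuzzier duplicate notions (same type within x metres)
  would need a distance parameter with no principled default.
- Light facilities are excluded from accessibility counting by default
  (`AnalysisConfig.include_light` retains them); in the motivating
  setting they were a fraction of a percent of the register.

## Network model and journey times

Coordinates are planar metres (a projected national-grid-like CRS); there
is no geodesy, no topography and no congestion. Directed links carry
length, road class (motorway, A, B, minor, local) and per-mode
permissions.

- **Walk / cycle**: constant speeds of 5 and 14 km/h; forbidden links
  (motorways) removed; route choice minimises *distance*, and time is the
  chosen distance at the mode speed. Hence cycle time ≡ (5/14) × walk
  time pair-wise — a structural invariant the tests assert.
- **Car**: free-flow speeds per road class (defaults 112/80/64/48/32
  km/h, configurable — the class hierarchy is given, the speeds are
  placeholders) and junction turn penalties (defaults left 6 s, right
  9 s, configurable placeholders; tests never depend on the values).
  A movement is straight when the signed bearing change is within ±30°,
  otherwise left (counter-clockwise) or right. Penalties are paid inside
  an edge-based Dijkstra, so a turn-free detour can beat a shorter
  turning route; post-hoc penalisation would miss such routes.
- **Bus**: a time-expanded search over (trip, stop) departure events.
  Constraints: boardings − 1 ≤ 2 transfers, access and egress walks ≤ 30
  minutes, wait at every boarding ≤ 5 minutes, departures inside the
  10:00–16:00 inter-peak window. The traveller is assumed to know the
  timetable, so the first wait is zero (arrival at the stop is timed) and
  the reported journey time excludes pre-window slack; the 20/30-minute
  accessibility thresholds therefore include interchange waits but no
  initial wait — a documented interpretation, since the source analysis
  does not state whether initial waits count. Interchange walks go
  through the walk graph and are not separately capped (only access and
  egress are). Walk-only itineraries never substitute for a bus journey:
  at least one ride link is required.
- **Off-network points** (population-weighted centroids, facilities)
  attach via a single dummy link to the Euclidean-nearest node, ties
  broken by lowest node id; dummy links are walked at walk speed (walk
  and bus) or driven at the slowest class speed (car).
- **Unreachable** is `inf` end to end, never a large finite number, so
  threshold counting cannot be corrupted.
- Determinism: shortest-by-distance ties are broken by the
  lexicographically smallest node-id sequence.

## Accessibility counts

Counts are cumulative opportunities: facilities of a given intensity with
travel time ≤ threshold (inclusive — "within 20 minutes" is read as a
closed bound). Population adjustment is facilities per 1,000 residents
(count × 1000 / population); the base is configurable. The adjustment
formula is this package's definition — the source tables' "adjusted"
columns are not accompanied by a formula, and per-1,000 scaling matches
their direction and magnitude for populations of 500–1,000.

## Statistical models

One model per stratum (urban / small town / rural) × intensity
(moderate, vigorous) × mode × threshold:

y_ij | b_j ~ Poisson(μ_ij) or NB2(μ_ij, α), with
log μ_ij = x_ij'β + log pop_ij + b_j and b_j ~ N(0, σ²) over local
authorities. Quintile dummies use Q1 (most affluent) as baseline;
population enters as a log offset, i.e. the model is of per-capita rates
("adjusting for population size" admits either an offset or a covariate;
the offset is the count-model convention and is the default here).

- **Estimation**: marginal maximum likelihood; the scalar random
  intercept is integrated by adaptive Gauss–Hermite quadrature (10 nodes
  by default, re-centred at each cluster's posterior mode with curvature
  scaling), optimised by BFGS from a single-level GLM start with a
  Nelder–Mead rescue. Deterministic, and accurate with as few as 2–8
  clusters, where Laplace-only approximations are at their weakest.
- **Intervals**: Wald, at the 99% level by default (z = 2.576); the
  conservative level mirrors the presence of residual spatial
  autocorrelation that the covariate below does not fully remove.
  Profile likelihood intervals were rejected for determinism and cost.
- **Family choice**: Poisson unless the Poisson fit's Pearson dispersion
  (at empirical-Bayes cluster intercepts) exceeds 1 *and* the LR test of
  NB vs Poisson is significant at 0.05 with the boundary-corrected null
  ½χ²₀ + ½χ²₁. Non-convergence falls back to negative binomial, flagged.
- **Spatial screening**: global Moran's I with binary shared-border
  weights; one-sided permutation p = (1 + #{I_perm ≥ I_obs})/(1 + B),
  B = 999 by default, seeded and recorded. When the pre-model test is
  significant at the 99% level, a spatial lag covariate
  log(1 + mean neighbouring response) is offered and kept only if it
  reduces residual |I| of the Pearson residuals. The log1p-of-neighbour-
  mean form is this package's assumption; the prior work it emulates does
  not print its exact definition.
- Degenerate cells (constant response, e.g. nothing reachable anywhere in
  a stratum) are reported with an explicit flag instead of rate ratios;
  strata under 30 zones or with a single local authority are fitted but
  flagged.

## Synthetic region generator

The generator states a world and keeps it fixed:

- **Geometry**: zones are cells of a perturbed rectangular lattice over a
  12 km square; border adjacency is exact by construction and equals
  shapely border-sharing (tested). Roads run along cell edges with a
  class hierarchy (central A-road spines, periodic B roads, alternating
  minor/local) plus one motorway chain closed to walking and cycling.
- **Populations**: uniform integers in [500, 1000] — the small-area
  design size of the emulated geography.
- **Deprivation**: an i.i.d. Gaussian field smoothed three times over the
  adjacency graph, cut into five equal-count quintiles; this guarantees
  five non-empty, spatially autocorrelated quintiles.
- **Urban–rural**: categories 1–6 assigned by ranked distance to the
  region core and split to the configured fractions (default
  0.70 / 0.13 / 0.17 urban / small town / rural, the emulated national
  mix), then collapsed 1–2 / 3–4 / 5–6.
- **Local authorities**: contiguous vertical bands of near-equal size
  (default 4).
- **Facilities**: an inhomogeneous Poisson process with zone intensity
  proportional to a configurable quintile rate ratio (defaults 1, 1.2,
  1.4, 1.6, 1.8 for Q1…Q5), normalised to a mean of 1.5 facilities per
  zone — the density of the emulated national register. Types are drawn
  from the shipped lookup.
- **Timetable**: routes follow shortest road paths between distant
  junctions, serving every second junction; trips run on a 30-minute
  headway inside 10:00–16:00 at 20 km/h in-vehicle, and only if they
  finish within the window.
- One seed drives everything through spawned substreams; a fixed
  configuration reproduces the bundle bit for bit, and the pipeline's
  artifact hashes are reproducible.

What the generator does *not* emulate: real geography (islands,
coastlines, disconnected components), census microdata, route quality or
topography, service reliability, or facility registers with attribute
noise. A green test therefore establishes that the machinery is correct
and calibrated on a faithful miniature, not that any particular empirical
gradient holds in a real region.

## Numerical choices

- Threshold comparison inclusive (≤); nearest-node and path ties broken
  by lowest id / lexicographic sequence; straight-movement threshold ±30°.
- Moran's I is undefined for constant values (explicit error) and is
  accepted for n ≥ 2 so the two-zone antithetic closed form (I = −1) is
  available as a check.
- Likelihood exponents are clipped at ±700/50 to keep wild optimiser
  line-search steps finite; σ and α are optimised as magnitudes.
- Permutation tests, quadrature and optimisation are all deterministic
  given seeds; default B = 999 permutations (199 in bulk calibration
  runs for speed, which leaves p-resolution 0.005 at α = 0.05).

## Known limitations

- The bus search assumes timed arrivals (zero first wait); results are
  therefore a best case for passengers with timetable knowledge.
- Wald intervals can be degenerate (infinite) for quintiles with zero
  counts in a stratum; these appear as RR 0 or inf with unbounded CIs
  and should be read as "no information", not as evidence.
- The car free-flow speeds and turn penalties are placeholders; absolute
  car times are only meaningful relative to a calibrated configuration.
- At desk scale the car mode often saturates (every facility reachable),
  making car models degenerate-constant — an honest property of a 12 km
  region, flagged rather than hidden.
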