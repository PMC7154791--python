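# Methods

## Scope and design

`bathyniche` implements an ensemble species-distribution workflow for
deep-sea benthic taxa: environmental layer construction, occurrence
quality control, pseudo-absence generation, three model families,
spatially blocked evaluation, metric-weighted ensembling with bootstrap
uncertainty, and dual-threshold projection of range change and climate
refugia. Because basin-scale occurrence databases and earth-system
model fields cannot ship with a library, the package carries a
first-class synthetic-data module: seeded oceans with known ground
truth against which every downstream stage is tested. The synthetic
world is a test instrument, not a simplification of the method — the
pipeline accepts real rasters (ESRI ASCII grid) and occurrence CSVs
through the same I/O surface.

## The synthetic ocean

`build_world(grid, seed)` generates, as a pure function of its inputs:

- **Bathymetry.** A west-coast elevation gradient plus
  Gaussian-filtered white noise (kernel width ≈ grid/25, configurable)
  is rank-mapped through a hypsometric profile `z = z_max · t²`
  (z_max = 4500 m), yielding ≈20% shelf (<200 m), a slope band, and
  ≈33% abyss (>2000 m) on an ocean mask of ≈85% of cells. Land is the
  lowest 15% of the elevation score.
- **Temperature** `1.5 + 8·exp(−z/800) + 5·southness + 1.5·η` (°C,
  smooth noise η). The latitude term persists at depth deliberately:
  temperature must correlate with depth (Spearman ρ ≈ −0.75, matching
  the strong but imperfect coupling in real bottom water) without being
  a pure depth proxy, so that the |ρ| > 0.85 collinearity screen
  removes depth but keeps temperature — the predictor-set outcome the
  workflow is designed to produce for corals.
- **Carbonate system.** Carbonate-ion concentration declines
  logarithmically with depth; the equilibrium concentrations for
  aragonite and calcite rise with pressure (exp(z/8000), calcite lower).
  Both Ω fields therefore decline monotonically with depth
  (|ρ(Ω, z)| > 0.85 by construction) and cross Ω = 1 inside the
  domain, placing saturation horizons at realistic mid-depths
  (aragonite ≈ 1300 m on default worlds).
- **POC flux.** Export flux at 100 m is lognormal
  (20·exp(0.9 η + 0.4·(1−southness)) mg C m⁻² day⁻¹) with strong
  mesoscale variance so that seafloor flux — attenuated by the Martin
  curve — is food-supply information, not a second depth proxy.
- **Dissolved oxygen** with a mid-depth minimum zone, and **pH**
  declining with depth.
- **Terrain derivatives** (slope, standardized BPI) computed from the
  bathymetry by the same functions real rasters would pass through.

Cells where any derived layer is undefined (e.g. an isolated ocean
pocket with an empty BPI annulus) are masked everywhere, so the stack
carries one consistent ocean mask.

The **future scenario** is a per-covariate affine transform. The
default emulates an end-of-century high-emissions trajectory at the
seafloor: +2 °C bottom warming, ×0.55 POC flux (within the projected
40–55% decline), ×0.85 on both saturation states (horizon shoaling),
×0.963 dissolved oxygen, −0.3 pH. Masked cells are untouched;
untransformed covariates are bit-identical.

**Niches** are products of per-covariate responses (Gaussian or
sigmoid) times a maximum prevalence. The default coral-like niche is
Gaussian in temperature around mid-depth (400–1800 m) conditions,
sigmoid-increasing in Ω_ar around the horizon (scale 0.12), and
sigmoid-increasing in POC flux — the combination the default scenario
erodes. A `strength` factor narrows all breadths at once; recovery
tests use strength 1.5 ("strong niche"). Presences are Bernoulli
draws per cell with acceptance probability equal to the true
suitability, repeated until the target count accrues, at most one
presence per cell (mirroring cell-level presence data). Corruption
(missing depths, depth mismatches sized to exceed both QC tolerances,
coarse positions assigned to the VME-portal source) is applied to
disjoint record subsets at exactly `round(frac · n)` counts.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: real coastline and seamount geometry,
water-mass structure and fronts, sampling bias in occurrence effort
(presences here are unbiased draws from the niche), taxonomic
uncertainty, spatial autocorrelation in residual species occupancy
beyond what the environment induces, and inter-ESM disagreement (one
deterministic delta stands in for an ensemble of climate models).

## Key parameter defaults

| Parameter | Default | Where |
|---|---|---|
| grid cell size | 3000 m (9 km² cells) | `GridSpec` |
| Martin export depth / exponent | 100 m / −0.858 | `MartinParams` |
| BPI annulus | inner 3, outer 25 cells | `TerrainParams` |
| depth-consistency tolerances | 30% relative AND 50 m absolute | `depth_consistency_filter` |
| positional accuracy bound | 5000 m (VME-portal records) | `position_accuracy_filter` |
| pseudo-absence counts | 10,000 corals / 100,000 fishes | `N_PSEUDO_ABSENCE` |
| presence buffer | 6 km (planar, centre-to-centre, boundary excluded) | `sample_background` |
| depth strata | 250 m bins over the occupied range | `default_strata_edges` |
| collinearity thresholds | Spearman 0.85, VIF 10 | `PredictorPolicy` |
| GAM basis dimension | 4 (3 for temperature and Ω in coral models) | `SmoothSpec` |
| RF | 500 trees, mtry = ⌊√p⌋ | `fit_rf` |
| CV | 4 blocks, 10 iterations, 80% training subsample | `cv_run` |
| importance permutations | 10 | `permutation_importance` |
| bootstrap replicates | 100, label-stratified | `bootstrap_uncertainty` |
| thresholds | P10 and MSS, both always reported | `change_maps` |

## Numerical and procedural choices

- **Environmental profiling** is a per-covariate envelope: the
  [2.5, 97.5] percentile box of presence covariate values, widened
  until it jointly covers ≥95% of presence cells, then padded outward
  by one box-width per side. The pad plays the role of the support
  margin a one-class profiling estimator places around its sample: it
  keeps clearly unreachable environments ineligible (a 15 °C cell when
  presences sit at 4–6 °C) while leaving the background broad enough
  to span the *decline* of suitability in every direction — without it
  the background is so niche-like that no model family can separate
  the classes, and predictions cannot rank cells outside the presence
  envelope. A raw quantile box is available by passing `margin=0`.
- **Maxent realization.** L1-regularized logistic presence–background
  model (liblinear, C = 1) over linear + quadratic + hinge features
  (5 forward + 5 reverse hinges per covariate on the [0,1]-scaled
  range), with the intercept shifted from the training class balance
  to the stated prevalence n₁/n₀ (clipped into (0,1) when presences
  outnumber absences). The output is a logistic-scale ranking index,
  not a probability of presence.
- **GAM.** Penalty-free regression splines: B-spline bases of fixed
  dimension (cubic for dimension ≥4, quadratic for 3; interior knots at
  training quantiles; one column dropped per smooth against the global
  intercept), fitted by binomial IRLS. Covariate subsets are compared
  exhaustively by AIC up to 8 candidates, by forward AIC beyond.
  Prediction covariates are clipped to the training range, so
  extrapolated cells take the boundary response.
- **RF HSI.** scikit-learn's `predict_proba` averages per-tree leaf
  probabilities; with fully grown trees leaves are (near-)pure, so
  this equals the presence vote fraction.
- **Blocked CV.** Blocks split at the median latitude, then at each
  half's median longitude; every block must hold 15–35% of points.
  Test blocks are drawn uniformly with replacement across iterations;
  thresholds are computed on the training data of each iteration; the
  held-out block is evaluated in full (the 80% subsample applies to the
  training side). An iteration whose test block is single-label is
  skipped and logged; more than 5 skips is an error.
- **P10** uses the type-7 (linear-interpolation) quantile, so with
  distinct scores and n a multiple of 10 the training sensitivity is
  exactly 0.90. **MSS** scans midpoints between adjacent distinct
  scores, ties resolved to the lowest threshold. Binarization uses
  `HSI ≥ threshold`.
- **Accuracy classes** (good / moderate / poor) follow the standard
  AUC / TSS cut-offs; when the two metrics disagree the worse class
  wins.
- **Ensemble weights** are normalized (AUC + TSS)/2 per family, using
  blocked-CV means at the MSS threshold (TSS is threshold-dependent);
  AUC-only and TSS-only weighting are available behind the same
  function. Per-cell ensemble uncertainty averages the family CV
  grids with the same weights (rather than pooling bootstrap maps).
- **Bootstrap** resamples rows with replacement stratified by label,
  so every replicate keeps the training prevalence and no replicate
  degenerates to a single class. Cells with mean HSI < 1e-6 report no
  CV.
- **Downscaling** regresses the coarse field on depth (linear drift)
  and kriges the residuals with an exponential variogram fitted to the
  binned empirical semivariance; with a zero nugget, sample cells are
  exact (enforced directly, since pure-nugget residual fields leave
  the kriging system ill-conditioned). Variogram fit failure falls
  back to inverse-distance-weighted residuals, logged.
- **Slope** uses the 3×3 Horn stencil (the de-facto GIS standard);
  **BPI** is positive on crests (elevation minus annulus-mean
  elevation) and z-scored over the mask, with truncated annuli at
  edges; a constant raw field is a standardization error, not a zero
  map.
- **Layer validation** reports √(adjusted R²) of a linear fit of
  observed on modelled by default (a plain Pearson correlation behind
  `mode="correlation"`), plus RMSE on the raw differences.
- **Seeding.** Every stage draws from `default_rng` on a stage-scoped
  seed, `sha256(master_seed:stage) mod 2³¹−1`, so inserting a stage
  never perturbs later stages; all seeds stay below 2³¹.

## Open design points, resolved

- The 30% depth tolerance is taken relative to the raster depth (the
  reference standard); the conjunction with the 50 m absolute
  tolerance means only records failing *both* tests are rejected.
- The positional-accuracy rule is read as "records whose positional
  error exceeds 5000 m are excluded"; the literal inverse (excluding
  the accurate records) is not sensible.
- Depth stratification defaults to the per-species presence depth
  distribution (self-contained); pooling across species is the
  caller's choice of `presence_depths`.
- The buffer metric is planar Euclidean on the equal-area grid; cells
  at exactly 6 km are excluded.
- The pairwise-Spearman pass runs before the VIF loop, strongest pair
  first, the lower-priority member dropped — deterministic and
  replayable from the decision log.
- MSS thresholds are computed on training data within each CV
  iteration (test data stay untouched until evaluation).

## Problem sizes

The test suite exercises the pipeline at desk scale: a 200×200-cell
basin (≈34,000 ocean cells) with 1000 presence cells and 5000
background cells for the recovery, importance, projection and null
checks; a 300×300 basin for the full 10,000-pseudo-absence coral
design; 100–150-cell worlds for module tests. These sizes keep the
suite to about a minute while preserving every structural property the
stages depend on (depth-zone coverage, collinearity structure,
stratification feasibility). The acceptance script uses the 200×200
configuration.

## Known limitations

- Maxent feature classes and the regularization constant are a
  reasonable default realization, not a reimplementation of any
  specific software's feature tuning.
- The GAM's fixed-dimension splines have no smoothing penalty; with
  the small basis dimensions used here that is the intended guard
  against overfitting, but it is not penalized-likelihood smoothing.
- Kriging downscaling fits an isotropic exponential variogram only.
- Latitude is affine in the row index; median-latitude summaries are
  exact on this frame but the grid does not model great-circle
  geometry.
- Binary-map areas count cells × 9 km²; no coastline clipping or
  exclusion polygons are applied.
- The uncertainty grid reflects resampling variance of each family's
  fit, not structural disagreement between climate forcings.
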