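# Methods

This note documents the models and procedures implemented in `noiselur`, the
defaults and why they were chosen, and what the synthetic fixtures can and
cannot demonstrate.

## Grid conventions and I/O

All rasters share a planar metric grid, default 10-m cells, row 0 north.
The cell center of (row r, col c) is
`(origin_x + (c+0.5)·cs, origin_y − (r+0.5)·cs)`; cell extents are half-open
`[x, x+cs)`. Zone and stratum membership is decided by cell center
(point-in-polygon), a single unambiguous rule. Coordinates are assumed
already projected to meters; no CRS machinery is included. Rasters are
stored as single-band ESRI ASCII grids written at full float64 precision
(`%.17g`), so a write/read round trip is value-exact; vectors are GeoJSON.

Road features use the six functional OSM types (motorway, trunk, primary,
secondary, tertiary, residential) as traffic proxies. Unmapped `highway`
values — including `*_link` ramps and `service` roads — are dropped with a
logged count; `lanes` defaults to 1; tunnel segments are retained in the
container but carry no emission weight anywhere downstream (rasterized
length, proximity, the acoustic fixture).

Road-length rasterization clips each polyline piece against the grid lines
analytically (crossing parameters with every vertical/horizontal grid line,
sub-segments assigned by midpoint), so the per-cell lengths are exact and
total length × lanes is conserved to rounding.

## Predictor space

* **Proximity**: Euclidean distance from the cell center to the nearest
  non-tunnel segment of each type, transformed as `log10(d + 1)`. The +1 m
  offset makes on-road cells map to exactly 0, matching the convention of
  log-transforming distances that start at 0 m. With no segment of a type,
  the column becomes a constant grid-diagonal sentinel and is flagged.
* **Focal statistics**: circular windows by center-to-center distance at the
  radii 12.5, 25, 50, 100, 200, 400, 800, 1600 m (log-spaced like noise
  attenuation; a 12.5-m radius on a 10-m grid is the rook neighborhood).
  Sums are plain truncated-at-edge window sums; means divide by the count of
  in-domain, non-nodata window cells, so edges are normalized. Convolutions
  run via FFT; window *counts* are re-rounded to integers afterwards, which
  keeps count-derived quantities (land-cover fractions) exact — the seven
  fractions partition 100% at every cell to float precision.
* **TPI**: center value minus neighborhood mean, center *excluded* from the
  mean, computed for building heights and the DEM. Positive = locally
  elevated. The sign convention follows the standard topographic position
  index (positive ridges, negative valleys); exclusion of the center is a
  free choice (a flat raster gives 0 either way) and is documented here
  because the peak response differs by a known factor.
* **Land-cover fractions**: percent of in-window cells per class of a
  7-class scheme (artificial, open soil, high/low × seasonal/perennial
  vegetation, water).
* Lane weighting applies to length features only, not to proximity.

The full candidate stack is 6 proximity columns + 15 windowed variables
(6 road lengths, 2 TPIs, 7 land-cover fractions) × 8 radii = 126 columns;
road lengths are reported in km.

## Radius selection

For each windowed variable, an intercept+slope OLS of sampled Lden on the
variable is fitted at every radius; the radius with the smallest in-sample
RMSE wins, ties toward the smallest radius. This is deliberately a simple
a-priori univariate screen — no wrapper/stepwise selection — run once on a
reference draw and reused by all campaigns, so the predictor set is held
constant across the experiment grid. Zero-variance columns at a radius are
skipped with a warning (on small scenes the largest windows can cover the
whole grid and become constant). When every variable survives, the reduced
stack has 6 + 15 = 21 columns.

## Sampling schemes

* **random** — uniform without replacement over valid cells.
* **systematic** — square lattice with spacing `s = √(valid_area / N)`; the
  seed maps to a uniform 2-D offset in `[0, s)²`; lattice points snap to
  their containing valid cell, duplicates are merged, and a rare edge-effect
  overshoot beyond N is trimmed by a seeded uniform drop, so
  `N_sampled ≤ N` always holds.
* **stratified_lden** — equal quotas over 5-dB(A) bins
  (`bin = floor(v/5)`, left-closed, anchored at 0).
* **stratified_landuse** — equal quotas over settlement-structure classes.

Stratified allocation is `floor(N/K)` per non-empty stratum with the
remainder given to the largest strata; a stratum smaller than its quota
contributes all its cells, which is exactly how `N_sampled` falls short of
`N` when loud bins are scarce. Equal (not proportional) allocation is the
point of stratification here: proportional quotas would reduce to random
sampling.

Representativity is a pooled-variance two-sided t-test of the sample against
*all* valid population cells. Zero pooled variance degenerates to p = 1 on
equal means, else 0 (logged).

## Model and validation

The LUR is plain OLS with classical (non-robust) standard errors, t and
two-sided p values. Zero-variance columns are dropped with a logged
manifest and reported as 0-coefficient placeholders so prediction stays
aligned; a rank-deficient design raises by default, naming the collinear
columns via pivoted QR. Campaign runs opt into `drop_collinear=True`
because small draws produce exact collinearity structurally — e.g. when all
seven land-cover fractions select the same radius their sum is identically
100, aliasing the intercept. Metrics: R² = 1 − SSres/SStot,
adj R² = 1 − (1−R²)(n−1)/(n−p−1), RMSE = √(SSres/n), MAE. Predictions are
never clipped; extrapolation beyond the training range is intentional.

Cross-validation:

* **LOOCV** via the exact hat-matrix identity
  `ŷ₋ᵢ = yᵢ − eᵢ/(1 − hᵢᵢ)` — algebraically identical to n refits (verified
  against explicit refits in the tests) and O(1) per sample. A leverage of
  exactly 1 makes the left-out prediction non-unique; such runs error and
  are recorded as missing by the campaign driver rather than fabricated.
* **LGOCV** — a random fraction (10/25/50%) held out, refit, repeated
  (default 20 repeats, seeded); metrics averaged into mean ± sd.
* **LSOCV** — one fold per admin district or settlement class; the summary
  averages per-fold metrics (a pooled-prediction R² is also reported for
  transparency). Folds whose training set cannot identify the model are
  skipped with a logged reason; small zones are expected.
* The robustness rule flags a model when `R²_overall − R²_CV ≥ 0.15`
  (strict `<` passes).

Campaign records are one row per (scheme, N, seed); failed fits carry a
`failed` flag, never silent drops. Aggregation reports mean, sd and the
5th/95th percentiles (linear interpolation between order statistics) per
scheme × size. Campaigns are independent by construction; execution order
cannot affect results.

## Synthetic scenes and the acoustic fixture

`generate_scene` builds a river-valley town from one integer seed: a DEM
with a valley carved along a meandering river plus smoothed noise; a road
hierarchy touching all six types (motorway across the north with a tunnel
section, trunk into the center, primary roads on both river banks,
secondary/tertiary connectors, residential street grids); building blocks
beside the residential streets; a 7-class land-cover mosaic; a 3 × 3 admin
tiling and a 4 × 4 settlement-structure tiling labeled by dominant surface.
Residential neighborhoods are placed away from the trunk/motorway corridors
so that quiet street types remain quieter than busy ones — without this the
background of the loud corridors would mask the residential emission class.

`simulate_lden` decomposes every non-tunnel segment into point sources every
`source_spacing` (default 10 m). Each source contributes

```
Lᵢ = E_type + 10·log10(spacing) − γ·log10(max(dᵢ, d0)/d0) − ground − shield
```

and the cell total is the energetic sum `10·log10(Σ 10^(Lᵢ/10))`. Defaults:
`d0 = 1 m`, spreading `γ = 20` dB/decade, per-type emissions pinned to
typical on-road mean Lden of the six functional classes (83.90, 76.37,
73.14, 68.00, 60.13, 51.44 dB(A)), which preserves the motorway > … >
residential hierarchy by construction. The ground term approximates
absorption over vegetated paths as `5 dB/km × d × veg_fraction(receiver)`
with the vegetation fraction from a 90-m smoothed map at the receiver — a
proxy for the true vegetated path length. Building shielding applies a
fixed 3-dB penalty when the straight source–receiver path crosses a
built-up cell, probed at the path midpoint and 15 m before the receiver
rather than by a full ray march. These are deliberate fixture
simplifications: the fixture gives a deterministic ground truth in which
proximity, density, terrain and land-cover effects are *recoverable*; it
makes no claim to engineering-standard propagation (no reflections,
meteorology, diffraction or terrain screening).

Consequences for interpretation: passing tests show the pipeline recovers
structure the fixture encodes and reproduces the *qualitative* experiment
patterns (stratified-Lden overestimation, scatter shrinking with N,
spatially blocked CV harsher than LOOCV). They do not certify accuracy
levels on real noise maps — the fixture's R² is substantially higher than
what heterogeneous real data yields, because the fixture's physics lives in
(nearly) the same function class the LUR fits.

`generate_linear_lden` is the second fixture: Lden = β₀ + Xβ + N(0, σ) on
the masked cells, used for exact (σ = 0, 1e-8 relative) and statistical
(σ = 5 dB, 10 000 cells, 3-SE coverage over 100 replicates) parameter
recovery.

## Numerical choices and degenerate inputs

* FFT focal sums re-round integer counts (exactness); non-integer sums keep
  ~1e-12 relative FFT error, asserted at 1e-9 tolerances.
* Radius-selection ties break toward the smallest radius deterministically.
* ANOVA across road types with zero between-group variation returns F = 0,
  p = 1 by convention; types with < 2 on-road cells are excluded with a
  warning.
* Zero-variance response makes R² undefined (NaN), not ±inf.
* All randomness flows through integer seeds (`numpy.random.default_rng`);
  identical inputs reproduce byte-identical CSV/JSON outputs.

## Problem sizes used in the checks

The test suite and acceptance script run on synthetic scenes of 100–300
cells per side. The scaled-down campaign experiment uses 4 schemes ×
N ∈ {50, 200, 1000} × 20 seeds on a 300 × 300 scene (9 × 9 km), with LOOCV
and admin-blocked LSOCV per campaign; the full reference grid
(4 × 5 × 100 = 2000 campaigns) is enumerated and its bookkeeping tested,
while the distributional assertions are made on the reduced grid. These
sizes were chosen so the whole experiment remains a desk-scale computation
while every qualitative contrast of interest is still measurable.

## Known limitations

* The acoustic fixture's shielding probe can miss thin obstacles between
  the two probe points; it is a structural, not physical, device.
* LSOCV per-fold R² is noisy for small zones (few samples → R² can be
  arbitrarily negative); prefer the pooled-prediction R² when folds are
  small.
* Equal-allocation stratification with very many strata and small N leaves
  single-cell quotas; representativity of such draws is poor by design.
* No support for multi-band imagery, CRS transformations, or OSM PBF
  parsing; inputs are expected pre-projected and pre-cut.
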