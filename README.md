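# noiselur

Scalable land-use-regression (LUR) mapping of road-traffic noise (Lden),
built around virtual-microphone sampling campaigns and spatially blocked
cross-validation.

## The problem

Strategic noise maps — engineering-grade Lden simulations at 10 × 10 m — exist
only where regulation mandates them. Everywhere else, epidemiologists need a
cheap way to estimate noise exposure. A land-use regression treats sampled
cells of an existing noise map as *virtual microphones* and learns

```
Lden(s) = β₀ + Σⱼ βⱼ xⱼ(s) + ε(s)
```

where the predictors xⱼ are geographic context at location s: log-transformed
distance to the nearest road of each functional type (motorway … residential),
lane-weighted road length inside circular moving windows, topographic position
indices (TPI) of building heights and terrain, and land-cover fractions — each
windowed variable at the radius (out of 12.5–1600 m) that minimizes the RMSE
of a bivariate pre-screen. The fitted model is then deployed cell-by-cell to
map noise beyond the original map's boundary.

Because noise is spatially structured, *how* the virtual microphones are
placed (random, systematic lattice, stratified by 5-dB noise bins or by
settlement class) and *how* the model is validated (leave-one-out vs leaving
out whole districts or settlement classes) decide whether the accuracy
numbers mean anything. This package makes the whole experiment grid —
schemes × sample sizes × seeds — reproducible on synthetic scenes with a
known acoustic ground truth.

## What's in the box

| module | role |
| --- | --- |
| `noiselur.geodata` | rasters (ESRI ASCII grid), GeoJSON roads/zones, exact road-length rasterization, zone labelling |
| `noiselur.scene` | synthetic study areas + acoustic Lden fixture (energetic point-source summation) + known-coefficient linear fixture |
| `noiselur.features` | log-proximity, focal sums/means, TPI, land-cover fractions; 126-column candidate stack |
| `noiselur.radii` | per-variable radius selection by bivariate RMSE (→ 21 columns) |
| `noiselur.sampling` | the four virtual-microphone schemes + pooled-t representativity test |
| `noiselur.model` | OLS with classical inference, R²/adj-R²/RMSE/MAE |
| `noiselur.crossval` | LOOCV (exact hat-matrix identity), repeated LGOCV, spatially blocked LSOCV, Eeftens ΔR² < 0.15 robustness rule |
| `noiselur.campaigns` | the (scheme × N × seed) experiment grid and its aggregation |
| `noiselur.mapping` | area-wide prediction, binned residuals, 55-dB(A) threshold shares and contours |
| `noiselur.cli` | `noiselur` command: `simulate-scene`, `build-features`, `select-radii`, `sample`, `fit`, `crossval`, `campaign`, `aggregate`, `predict`, `report` |

## Worked example

`examples/` contains one short script per capability. Running
`python examples/04_fit_and_crossvalidate.py` fits a LUR on 500
settlement-stratified virtual microphones of a 150 × 150 synthetic scene and
prints:

```
overall model on 500 samples: R2 = 0.942, adj R2 = 0.939, RMSE = 1.53, MAE = 1.09 dB(A)
intercept: 111.99 dB(A)

method            param  mean R2  robust?
loocv                      0.933     True
lgocv               0.1    0.930     True
lgocv               0.5    0.925     True
lsocv_admin                0.515    False
lsocv_landuse            -23.352    False
```

Reading: conventional CV (LOOCV, LGOCV) sits within 0.02 of the overall R²,
so by the ΔR² < 0.15 rule the model looks robust — but that only certifies
*interpolation*. Blocking by admin district (`lsocv_admin`) drops R² to 0.52,
and blocking by settlement class collapses it entirely: the model does not
transfer into kinds of areas it never saw. That gap between conventional and
spatially blocked CV is the central methodological point the package lets
you reproduce.

`examples/06_predict_and_report.py` then deploys the model area-wide:

```
predicted Lden spans 47.0-92.1 dB(A) (training range 48.6-86.5)
MAE: 1.12 dB(A) overall, 0.97 dB(A) in built-up cells
built-up cells within +/-2.5 dB(A): 96%
below the 55-dB(A) threshold: 12.8% of the area, 0.2% of built-up cells
```

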