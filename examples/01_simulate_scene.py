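"""Generate a synthetic study area and its reference road-noise raster.

The scene emulates a river-valley town: terrain, a six-type road hierarchy
(motorway down to residential streets, one motorway section in a tunnel),
building blocks, a 7-class land-cover mosaic and admin/settlement zones.
The acoustic fixture then produces an Lden raster by energetic summation of
per-road-type point sources.
"""

import noiselur as nl

scene = nl.generate_scene(seed=1, n_rows=150, n_cols=150)
lden = nl.simulate_lden(scene, nl.AcousticParams())

print(f"grid: {lden.n_rows} x {lden.n_cols} cells at "
      f"{lden.cell_size:.0f} m -> {lden.n_rows * lden.n_cols} cells")
print(f"Lden range {lden.values.min():.1f}-{lden.values.max():.1f} dB(A), "
      f"mean {lden.values.mean():.1f}, sd {lden.values.std():.1f}")

# On-road Lden per road type: the functional class is a usable proxy for
# emission only if the six types carry distinct levels (ANOVA below).
summary, f_stat, p = nl.road_type_summary(lden, scene.roads)
print("\non-road Lden by functional road type:")
print(summary[["min", "median", "mean", "sd", "max", "n"]].round(2).to_string())
print(f"\none-way ANOVA across types: F = {f_stat:.1f}, p = {p:.3g}")
print("-> the six types have clearly separated emission levels, so they can"
      "\n   stand in for traffic volume in the regression.")
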