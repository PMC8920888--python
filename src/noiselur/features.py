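"""Predictor engineering for the noise LUR.

The feature space mirrors common road-noise land-use-regression practice:

* per-road-type *proximity*, the Euclidean distance (m) from each cell center
  to the nearest non-tunnel segment, log-transformed as ``log10(d + 1)`` so
  that on-road cells map to 0;
* per-road-type *cumulated road length*, the lane-weighted rasterized length
  aggregated over circular moving windows (reported in km);
* *topographic position index* (TPI) of building heights and of the terrain:
  center value minus the neighborhood mean (center excluded), positive =
  locally elevated;
* *land-cover fractions* in percent per 7-class land cover.

All windowed features are computed at the eight systematically scaled radii
12.5, 25, 50, 100, 200, 400, 800 and 1600 m (circular windows by
center-to-center distance).  Window means are normalized by the number of
in-domain cells, so edges are handled gracefully; window sums are left
truncated at edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import signal, stats

from .geodata import ROAD_TYPES, RasterGrid, RoadNetwork

logger = logging.getLogger(__name__)

#: Canonical moving-window radii (m), log-spaced like noise attenuation.
RADII = (12.5, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0)

#: 7-class land cover: id -> short name.
LANDCOVER_CLASSES = {
    1: "artificial",
    2: "open_soil",
    3: "high_seasonal_veg",
    4: "high_perennial_veg",
    5: "low_seasonal_veg",
    6: "low_perennial_veg",
    7: "water",
}


@dataclass(frozen=True)
class FeatureSpec:
    """Metadata for one predictor column."""

    name: str
    source: str        # {"roads", "buildings", "dem", "landcover"}
    variable: str      # e.g. "motorway_proximity", "trunk_length", "tpi"
    aggregation: str   # {"none", "sum", "mean", "tpi", "fraction"}
    radius: float | None = None  # None for proximity features

    def __post_init__(self):
        if self.aggregation == "none" and self.radius is not None:
            raise ValueError("proximity features carry no radius")
        if self.aggregation != "none" and self.radius not in RADII:
            raise ValueError(f"radius {self.radius} not in the canonical set")


@dataclass
class FeatureStack:
    """An ordered set of predictor rasters sharing one grid geometry."""

    specs: list[FeatureSpec]
    columns: dict[str, np.ndarray]
    mask: np.ndarray
    grid: RasterGrid

    def __post_init__(self):
        if len(self.specs) != len(self.columns):
            raise ValueError("column count must equal spec count")
        for s in self.specs:
            if s.name not in self.columns:
                raise ValueError(f"missing column {s.name!r}")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def width(self) -> int:
        return len(self.specs)

    def matrix(self, rows: np.ndarray | None = None,
               cols: np.ndarray | None = None) -> np.ndarray:
        """Design matrix (n, width): all masked cells, or the given cells."""
        if rows is None:
            rr, cc = np.nonzero(self.mask)
        else:
            rr, cc = np.asarray(rows), np.asarray(cols)
        return np.column_stack([self.columns[n][rr, cc] for n in self.names])

    def select(self, names: Sequence[str]) -> "FeatureStack":
        """A reduced stack restricted to ``names`` (given order)."""
        by_name = {s.name: s for s in self.specs}
        specs = [by_name[n] for n in names]
        return FeatureStack(specs, {n: self.columns[n] for n in names},
                            self.mask, self.grid)

    def to_dir(self, path: str | Path) -> None:
        """Write one ``.asc`` per band plus a band-order manifest."""
        from .geodata import write_raster
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for s in self.specs:
            write_raster(self.grid.like(np.where(self.mask, self.columns[s.name],
                                                 self.grid.nodata)),
                         path / f"{s.name}.asc")
            rows.append({"name": s.name, "source": s.source, "variable": s.variable,
                         "aggregation": s.aggregation,
                         "radius": "" if s.radius is None else s.radius})
        pd.DataFrame(rows).to_csv(path / "manifest.csv", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "FeatureStack":
        from .geodata import read_raster
        path = Path(path)
        man = pd.read_csv(path / "manifest.csv", keep_default_na=False)
        specs, columns = [], {}
        grid = None
        for _, row in man.iterrows():
            radius = None if row["radius"] == "" else float(row["radius"])
            spec = FeatureSpec(row["name"], row["source"], row["variable"],
                               row["aggregation"], radius)
            g = read_raster(path / f"{row['name']}.asc")
            if grid is None:
                grid = g
            specs.append(spec)
            columns[spec.name] = g.values
        mask = np.ones(grid.shape, dtype=bool)
        for n, v in columns.items():
            mask &= ~np.isclose(v, grid.nodata)
        return cls(specs, columns, mask, grid)


# ---------------------------------------------------------------------------
# Elementary feature operators
# ---------------------------------------------------------------------------

def proximity_feature(roads: RoadNetwork, grid: RasterGrid,
                      road_type: str) -> RasterGrid:
    """log10(d + 1) of the distance (m) to the nearest non-tunnel segment.

    With no segment of the type present, a constant large-distance sentinel
    (the grid diagonal) is returned and flagged via a log warning.
    """
    net = roads.of_type(road_type)
    X, Y = grid.center_coords()
    if len(net) == 0:
        d_max = float(np.hypot(grid.n_cols, grid.n_rows) * grid.cell_size)
        logger.warning("no %s segments: proximity set to sentinel %.0f m",
                       road_type, d_max)
        d = np.full(grid.shape, d_max)
    else:
        geoms = np.array([s.geometry for s in net.segments], dtype=object)
        tree = shapely.STRtree(list(geoms))
        pts = shapely.points(np.column_stack([X.ravel(), Y.ravel()]))
        idx = tree.nearest(pts)
        d = shapely.distance(pts, geoms[idx]).reshape(grid.shape)
    return grid.like(np.log10(d + 1.0), units="log10(m)")


def _circular_kernel(radius: float, cell_size: float) -> np.ndarray:
    """0/1 window: cells whose center lies within ``radius`` of the focal center."""
    r_cells = int(np.floor(radius / cell_size + 1e-9))
    off = np.arange(-r_cells, r_cells + 1)
    dy, dx = np.meshgrid(off, off, indexing="ij")
    return ((dx ** 2 + dy ** 2) * cell_size ** 2
            <= radius ** 2 + 1e-9).astype(float)


def _focal_sum(values: np.ndarray, kernel: np.ndarray,
               integer: bool = False) -> np.ndarray:
    """FFT moving-window sum (zero-padded edges); integer inputs re-rounded."""
    out = signal.fftconvolve(values, kernel, mode="same")
    return np.rint(out) if integer else out


def focal_statistic(raster: RasterGrid, radius: float, stat: str = "mean",
                    kernel: np.ndarray | None = None) -> RasterGrid:
    """Circular moving-window sum or mean.

    Nodata cells contribute nothing; the mean divides by the count of
    in-domain, non-nodata window cells (so edges and gaps are normalized),
    while the sum is left truncated at edges.
    """
    if stat not in ("sum", "mean"):
        raise ValueError(f"stat must be 'sum' or 'mean', got {stat!r}")
    if kernel is None:
        kernel = _circular_kernel(radius, raster.cell_size)
    mask = raster.valid_mask
    vals = np.where(mask, raster.values, 0.0)
    s = _focal_sum(vals, kernel)
    if stat == "sum":
        return raster.like(s)
    cnt = _focal_sum(mask.astype(float), kernel, integer=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cnt > 0, s / np.maximum(cnt, 1), raster.nodata)
    return raster.like(out)


def tpi(raster: RasterGrid, radius: float,
        kernel: np.ndarray | None = None) -> RasterGrid:
    """Topographic position index: center minus neighborhood mean.

    The focal cell is excluded from the neighborhood mean; positive values are
    locally elevated ("superior") locations, negative values are valleys.
    """
    if kernel is None:
        kernel = _circular_kernel(radius, raster.cell_size)
    mask = raster.valid_mask
    vals = np.where(mask, raster.values, 0.0)
    s = _focal_sum(vals, kernel)
    cnt = _focal_sum(mask.astype(float), kernel, integer=True)
    # neighborhood = window minus the center cell itself
    nb_sum = s - vals
    nb_cnt = cnt - mask.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        nb_mean = np.where(nb_cnt > 0, nb_sum / np.maximum(nb_cnt, 1), vals)
    out = np.where(mask, raster.values - nb_mean, raster.nodata)
    return raster.like(out)


def landcover_fraction(landcover: RasterGrid, class_id: int, radius: float,
                       kernel: np.ndarray | None = None) -> RasterGrid:
    """Percent (0-100) of in-window cells carrying ``class_id``."""
    if class_id not in LANDCOVER_CLASSES:
        raise ValueError(f"unknown land-cover class {class_id}")
    if kernel is None:
        kernel = _circular_kernel(radius, landcover.cell_size)
    mask = landcover.valid_mask
    hit = (mask & (np.rint(landcover.values).astype(int) == class_id)).astype(float)
    n_hit = _focal_sum(hit, kernel, integer=True)
    n_all = _focal_sum(mask.astype(float), kernel, integer=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n_all > 0, 100.0 * n_hit / np.maximum(n_all, 1),
                       landcover.nodata)
    return landcover.like(out, units="%")


# ---------------------------------------------------------------------------
# Full candidate stack
# ---------------------------------------------------------------------------

def build_feature_stack(scene, radii: Sequence[float] = RADII) -> FeatureStack:
    """The full candidate predictor stack on a scene's grid.

    6 proximity columns (no radius) plus 15 windowed variables (6 road-length,
    building TPI, terrain TPI, 7 land-cover fractions) at every radius:
    6 + 15 x 8 = 126 candidate columns for the canonical radii set.
    Road-length columns are lane-weighted focal sums converted to km.
    """
    from .geodata import rasterize_road_length

    for layer in ("dem", "building_height", "landcover", "roads"):
        if getattr(scene, layer, None) is None:
            raise ValueError(f"scene is missing layer {layer!r}")
    grid = scene.dem
    radii = tuple(sorted(radii))
    kernels = {r: _circular_kernel(r, grid.cell_size) for r in radii}

    specs: list[FeatureSpec] = []
    columns: dict[str, np.ndarray] = {}

    def add(spec: FeatureSpec, values: np.ndarray):
        specs.append(spec)
        columns[spec.name] = values

    for t in ROAD_TYPES:
        g = proximity_feature(scene.roads, grid, t)
        add(FeatureSpec(f"{t}_proximity", "roads", f"{t}_proximity", "none"),
            g.values)

    length_rasters = {t: rasterize_road_length(scene.roads, grid, t)
                      for t in ROAD_TYPES}
    for t in ROAD_TYPES:
        for r in radii:
            g = focal_statistic(length_rasters[t], r, "sum", kernel=kernels[r])
            add(FeatureSpec(_radius_name(f"{t}_length", r), "roads",
                            f"{t}_length", "sum", r), g.values / 1000.0)

    for r in radii:
        g = tpi(scene.building_height, r, kernel=kernels[r])
        add(FeatureSpec(_radius_name("building_tpi", r), "buildings",
                        "building_tpi", "tpi", r), g.values)
    for r in radii:
        g = tpi(scene.dem, r, kernel=kernels[r])
        add(FeatureSpec(_radius_name("terrain_tpi", r), "dem",
                        "terrain_tpi", "tpi", r), g.values)

    for cid, cname in LANDCOVER_CLASSES.items():
        for r in radii:
            g = landcover_fraction(scene.landcover, cid, r, kernel=kernels[r])
            add(FeatureSpec(_radius_name(f"{cname}_fraction", r), "landcover",
                            f"{cname}_fraction", "fraction", r), g.values)

    mask = (scene.dem.valid_mask & scene.building_height.valid_mask
            & scene.landcover.valid_mask)
    return FeatureStack(specs, columns, mask, grid)


def _radius_name(base: str, radius: float) -> str:
    r = f"{radius:g}".replace(".", "p")
    return f"{base}_{r}"


# ---------------------------------------------------------------------------
# Road-type emission-proxy diagnostics
# ---------------------------------------------------------------------------

def road_type_summary(lden: RasterGrid, roads: RoadNetwork):
    """On-road Lden summary per road type plus a one-way ANOVA across types.

    A cell counts as on-road for a type when any non-tunnel segment of that
    type intersects it.  Types with fewer than 2 on-road cells are excluded
    from the ANOVA with a warning.

    Returns
    -------
    (summary, f_stat, p_value)
        ``summary`` is a DataFrame indexed by road type with columns
        min, q1, median, mean, sd, q3, max, n.
    """
    from .geodata import rasterize_road_length

    groups: dict[str, np.ndarray] = {}
    rows = []
    for t in ROAD_TYPES:
        onroad = rasterize_road_length(roads, lden, t).values > 0
        vals = lden.values[onroad & lden.valid_mask]
        if vals.size:
            groups[t] = vals
            rows.append({
                "road_type": t, "min": vals.min(),
                "q1": np.percentile(vals, 25), "median": np.median(vals),
                "mean": vals.mean(), "sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
                "q3": np.percentile(vals, 75), "max": vals.max(), "n": vals.size,
            })
    summary = pd.DataFrame(rows).set_index("road_type") if rows else pd.DataFrame()
    anova_groups = []
    for t, vals in groups.items():
        if vals.size < 2:
            logger.warning("road type %s has < 2 on-road cells; excluded from ANOVA", t)
        else:
            anova_groups.append(vals)
    if len(anova_groups) >= 2:
        allv = np.concatenate(anova_groups)
        if np.ptp(allv) == 0:
            # zero between-group variation: F = 0 by convention
            f_stat, p_value = 0.0, 1.0
        else:
            f_stat, p_value = stats.f_oneway(*anova_groups)
    else:
        f_stat, p_value = np.nan, np.nan
    return summary, float(f_stat), float(p_value)
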