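"""Synthetic study areas and reference Lden fixtures.

Every downstream stage (feature engineering, sampling campaigns, model
fitting, prediction mapping) is testable without external data through two
fixtures generated here:

* :func:`simulate_lden` — an *acoustic* fixture: each non-tunnel road segment
  is decomposed into point sources and levels combine energetically with
  log-distance spreading, a vegetation ground-absorption term and an optional
  building-shielding penalty.  Proximity, density, terrain and land-cover
  effects are therefore recoverable by a LUR, without pretending to implement
  an engineering-grade propagation standard.
* :func:`generate_linear_lden` — a *known-coefficient* linear fixture for
  exact parameter-recovery tests.

The scene layout emulates a mid-size river-valley town: a terrain valley
carved along a meandering river, a motorway skirting the north (with a tunnel
section), a trunk road into the center, primary roads along both river banks,
secondary/tertiary connectors and residential street grids surrounded by
building blocks.  Default per-type source emissions are calibrated to typical
on-road Lden means of the six functional OSM road types (motorway 83.9 dB(A)
down to residential 51.4 dB(A)), preserving the emission hierarchy
motorway > trunk > primary > secondary > tertiary > residential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from .geodata import (ROAD_TYPES, RasterGrid, RoadNetwork, RoadSegment, Zone,
                      ZoneSet, rasterize_road_length)

#: On-road mean Lden per functional road type, dB(A) — emission anchors.
DEFAULT_EMISSIONS = {
    "motorway": 83.90,
    "trunk": 76.37,
    "primary": 73.14,
    "secondary": 68.00,
    "tertiary": 60.13,
    "residential": 51.44,
}


@dataclass
class AcousticParams:
    """Tunables of the acoustic fixture.

    ``emission_by_type`` are source levels (dB(A)) at reference distance
    ``d0``; ``spreading_coefficient`` is the per-decade geometric decay
    (20 = cylindrical-to-spherical ballpark); ``ground_absorption`` is an
    extra loss in dB per km of vegetated propagation path;
    ``shielding_db`` is a fixed penalty when the source-receiver path crosses
    a built-up cell; ``source_spacing`` is the segment discretization step.
    """

    emission_by_type: dict = field(default_factory=lambda: dict(DEFAULT_EMISSIONS))
    d0: float = 1.0
    spreading_coefficient: float = 20.0
    ground_absorption: float = 5.0   # dB per km of vegetated path
    source_spacing: float = 10.0
    shielding_db: float = 3.0
    shielding: bool = True

    def __post_init__(self):
        if self.d0 < 1:
            raise ValueError("d0 must be >= 1 m")
        if self.source_spacing <= 0:
            raise ValueError("source_spacing must be > 0")
        e = self.emission_by_type
        order = [e[t] for t in ROAD_TYPES]
        if not all(a > b for a, b in zip(order[:-1], order[1:])):
            raise ValueError("emissions must be ordered motorway > ... > residential")


@dataclass
class Scene:
    """One complete synthetic study area on a shared 10-m grid."""

    dem: RasterGrid
    building_height: RasterGrid
    landcover: RasterGrid
    roads: RoadNetwork
    admin_zones: ZoneSet
    landuse_zones: ZoneSet
    seed: int

    @property
    def grid(self) -> RasterGrid:
        return self.dem


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def _smooth_field(rng, shape, sigma, scale=1.0):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd * scale if sd > 0 else f


def generate_scene(seed: int, n_rows: int, n_cols: int,
                   cell_size: float = 10.0) -> Scene:
    """A reproducible synthetic scene; all randomness flows through ``seed``.

    Raises if the grid is smaller than 50 x 50 — the road hierarchy does not
    fit below that.
    """
    if n_rows < 50 or n_cols < 50:
        raise ValueError("scene must be at least 50 x 50 cells for the road "
                         "hierarchy to fit")
    rng = np.random.default_rng(seed)
    W, H = n_cols * cell_size, n_rows * cell_size
    grid = RasterGrid(np.zeros((n_rows, n_cols)), origin_x=0.0, origin_y=H,
                      cell_size=cell_size, units="m")
    X, Y = grid.center_coords()

    # --- terrain: a valley carved along a meandering river ---------------
    phase = rng.uniform(0, 2 * np.pi)
    amp = 0.08 * W

    def river_x(y):
        return 0.60 * W + amp * np.sin(2 * np.pi * y / H + phase)

    dist_river = np.abs(X - river_x(Y))
    dem_vals = (60.0 + 0.05 * dist_river
                + _smooth_field(rng, grid.shape, sigma=max(n_rows, n_cols) / 12,
                                scale=8.0))
    dem = grid.like(dem_vals, units="m")

    # --- roads -----------------------------------------------------------
    segments: list[RoadSegment] = []

    def polyline(xs, ys):
        return np.column_stack([xs, ys])

    # motorway across the north, with a tunnel section mid-way
    my = 0.85 * H
    xs = np.linspace(0, W, 40)
    ys = my + 0.03 * H * np.sin(2 * np.pi * xs / W + rng.uniform(0, 2 * np.pi))
    cut1, cut2 = int(0.45 * len(xs)), int(0.55 * len(xs))
    segments.append(RoadSegment(polyline(xs[:cut1 + 1], ys[:cut1 + 1]),
                                "motorway", lanes=4))
    segments.append(RoadSegment(polyline(xs[cut1:cut2 + 1], ys[cut1:cut2 + 1]),
                                "motorway", lanes=4, tunnel=True))
    segments.append(RoadSegment(polyline(xs[cut2:], ys[cut2:]),
                                "motorway", lanes=4))

    # trunk: from the motorway south into the center
    ty = np.linspace(my, 0.40 * H, 25)
    tx = 0.50 * W + 0.02 * W * np.sin(2 * np.pi * ty / H * 2 + rng.uniform(0, 6))
    segments.append(RoadSegment(polyline(tx, ty), "trunk", lanes=3))

    # primary roads along both river banks
    for side in (-1.0, 1.0):
        py = np.linspace(0, H, 40)
        px = river_x(py) + side * 3.0 * cell_size
        segments.append(RoadSegment(polyline(px, py), "primary", lanes=2))

    # secondary connectors east-west
    for fy in (0.30, 0.60):
        sy = fy * H + rng.uniform(-0.02, 0.02) * H
        sx = np.linspace(0.10 * W, 0.90 * W, 20)
        syy = sy + 0.01 * H * np.sin(2 * np.pi * sx / W * 3)
        segments.append(RoadSegment(polyline(sx, syy), "secondary", lanes=2))

    # tertiary connectors
    for fx in (0.20, 0.35, 0.75):
        tx2 = fx * W + rng.uniform(-0.02, 0.02) * W
        ty2 = np.linspace(0.10 * H, 0.70 * H, 15)
        txx = tx2 + 0.01 * W * np.sin(2 * np.pi * ty2 / H * 2)
        segments.append(RoadSegment(polyline(txx, ty2), "tertiary", lanes=1))

    # residential street grids in a few neighborhoods, kept off the loud
    # trunk/motorway corridors so quiet streets stay quiet
    n_hoods = 3 if max(n_rows, n_cols) < 200 else 4
    hood_centers = np.column_stack([
        rng.uniform(0.10 * W, 0.38 * W, n_hoods),
        rng.uniform(0.12 * H, 0.48 * H, n_hoods),
    ])
    hood_half = max(6 * cell_size, 0.05 * min(W, H))
    for cx, cy in hood_centers:
        n_streets = rng.integers(3, 6)
        offsets = np.linspace(-hood_half, hood_half, n_streets)
        for off in offsets:  # parallel streets
            segments.append(RoadSegment(
                polyline([cx - hood_half, cx + hood_half], [cy + off, cy + off]),
                "residential", lanes=1))
        for off in offsets[::2]:  # cross streets
            segments.append(RoadSegment(
                polyline([cx + off, cx + off], [cy - hood_half, cy + hood_half]),
                "residential", lanes=1))
    roads = RoadNetwork(segments)

    # --- buildings: blocks beside residential streets, denser downtown ---
    res_len = rasterize_road_length(roads, grid, "residential").values
    near_res = ndimage.binary_dilation(res_len > 0, iterations=3)
    on_street = res_len > 0
    lots = near_res & ~on_street & (rng.random(grid.shape) < 0.55)
    heights = np.where(lots, rng.gamma(4.0, 2.5, grid.shape), 0.0)
    building_height = grid.like(heights, units="m")

    # --- land cover: 7-class mosaic --------------------------------------
    lc = np.zeros(grid.shape, dtype=int)
    veg_split = _smooth_field(rng, grid.shape, sigma=max(n_rows, n_cols) / 10)
    seas_split = _smooth_field(rng, grid.shape, sigma=max(n_rows, n_cols) / 14)
    soil_field = _smooth_field(rng, grid.shape, sigma=max(n_rows, n_cols) / 20)
    high_veg = veg_split > 0.2
    seasonal = seas_split > 0.0
    lc[high_veg & seasonal] = 3
    lc[high_veg & ~seasonal] = 4
    lc[~high_veg & seasonal] = 5
    lc[~high_veg & ~seasonal] = 6
    lc[soil_field > 1.3] = 2
    any_road = np.zeros(grid.shape, dtype=bool)
    for t in ROAD_TYPES:
        any_road |= rasterize_road_length(roads, grid, t).values > 0
    artificial = ndimage.binary_dilation(any_road, iterations=1) | (heights > 0)
    lc[artificial] = 1
    lc[dist_river < 2.0 * cell_size] = 7  # the river wins over everything
    landcover = grid.like(lc.astype(float), units="class")

    # --- zones ------------------------------------------------------------
    admin_zones = _tile_zones(grid, 3, 3, "admin", prefix="district")
    landuse_zones = _landuse_zones(grid, landcover, building_height, n_tiles=4)

    return Scene(dem=dem, building_height=building_height, landcover=landcover,
                 roads=roads, admin_zones=admin_zones,
                 landuse_zones=landuse_zones, seed=int(seed))


def _tile_zones(grid: RasterGrid, nx: int, ny: int, kind: str,
                prefix: str, labels: list[str] | None = None) -> ZoneSet:
    """Rectangular tiling of the grid extent, boundaries on cell edges."""
    W = grid.n_cols * grid.cell_size
    H = grid.n_rows * grid.cell_size
    xs = [round(i * grid.n_cols / nx) * grid.cell_size for i in range(nx + 1)]
    ys = [round(j * grid.n_rows / ny) * grid.cell_size for j in range(ny + 1)]
    zones = []
    k = 0
    for j in range(ny):
        for i in range(nx):
            poly = Polygon([(xs[i], ys[j]), (xs[i + 1], ys[j]),
                            (xs[i + 1], ys[j + 1]), (xs[i], ys[j + 1])])
            label = labels[k] if labels else f"{prefix}_{k}"
            zones.append(Zone(id=f"{prefix}_{k}", label=label, polygon=poly))
            k += 1
    return ZoneSet(zones, kind=kind)


def _landuse_zones(grid: RasterGrid, landcover: RasterGrid,
                   building_height: RasterGrid, n_tiles: int = 4) -> ZoneSet:
    """Settlement-structure zones: tiles labeled by their dominant surface.

    Mimics an urban-atlas-style classification: dense built-up, built-up,
    forest, open land, water-side — the labels used for land-use stratified
    sampling and for spatially blocked cross-validation.
    """
    lc = np.rint(landcover.values).astype(int)
    built = building_height.values > 0
    nx = ny = n_tiles
    labels = []
    row_edges = [round(j * grid.n_rows / ny) for j in range(ny + 1)]
    col_edges = [round(i * grid.n_cols / nx) for i in range(nx + 1)]
    for j in range(ny):
        for i in range(nx):
            sl = (slice(grid.n_rows - row_edges[j + 1], grid.n_rows - row_edges[j]),
                  slice(col_edges[i], col_edges[i + 1]))
            tile_lc = lc[sl]
            built_frac = built[sl].mean()
            art_frac = (tile_lc == 1).mean()
            forest_frac = np.isin(tile_lc, (3, 4)).mean()
            water_frac = (tile_lc == 7).mean()
            if built_frac > 0.08:
                labels.append("dense_builtup")
            elif art_frac > 0.10:
                labels.append("builtup")
            elif water_frac > 0.05:
                labels.append("waterside")
            elif forest_frac > 0.5:
                labels.append("forest")
            else:
                labels.append("open_land")
    return _tile_zones(grid, nx, ny, "landuse", prefix="lu", labels=labels)


def save_scene(scene: Scene, out_dir) -> None:
    """Write all scene layers (rasters as .asc, vectors as GeoJSON)."""
    from pathlib import Path
    from .geodata import write_raster, write_roads, write_zones
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_raster(scene.dem, out / "dem.asc")
    write_raster(scene.building_height, out / "building_height.asc")
    write_raster(scene.landcover, out / "landcover.asc")
    write_roads(scene.roads, out / "roads.geojson")
    write_zones(scene.admin_zones, out / "admin_zones.geojson")
    write_zones(scene.landuse_zones, out / "landuse_zones.geojson")


def load_scene(scene_dir, seed: int = -1) -> Scene:
    from pathlib import Path
    from .geodata import read_raster, read_roads, read_zones
    d = Path(scene_dir)
    return Scene(
        dem=read_raster(d / "dem.asc", units="m"),
        building_height=read_raster(d / "building_height.asc", units="m"),
        landcover=read_raster(d / "landcover.asc", units="class"),
        roads=read_roads(d / "roads.geojson"),
        admin_zones=read_zones(d / "admin_zones.geojson", kind="admin"),
        landuse_zones=read_zones(d / "landuse_zones.geojson", kind="landuse"),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Acoustic fixture
# ---------------------------------------------------------------------------

def _point_sources(roads: RoadNetwork, spacing: float):
    """Decompose non-tunnel segments into (x, y, emission-key) point sources."""
    xs, ys, types = [], [], []
    for seg in roads.emitting().segments:
        geom = seg.geometry
        L = geom.length
        if L == 0:
            continue
        for d in np.arange(spacing / 2.0, L, spacing):
            p = geom.interpolate(d)
            xs.append(p.x)
            ys.append(p.y)
            types.append(seg.road_type)
    return np.asarray(xs), np.asarray(ys), types


def simulate_lden(scene: Scene, params: AcousticParams | None = None) -> RasterGrid:
    """Reference Lden by energetic summation of per-road-type point sources.

    Each source contributes
    ``L_i = E_type + 10 log10(spacing) - gamma log10(max(d, d0)/d0)
    - ground - shielding`` and the cell total is ``10 log10(sum 10^(L_i/10))``.
    The ground term approximates absorption over vegetated paths as
    ``ground_absorption * d_km * veg_fraction`` with the vegetation fraction
    taken from a smoothed map at the receiver; shielding probes the straight
    path at its midpoint and 15 m before the receiver and applies a fixed
    penalty when a probe falls in a built-up cell.  Deliberately simple
    fixture physics: enough structure for a LUR to recover, no
    engineering-standard claims.
    """
    params = params or AcousticParams()
    grid = scene.grid
    X, Y = grid.center_coords()
    rx, ry = X.ravel(), Y.ravel()
    sx, sy, stypes = _point_sources(scene.roads, params.source_spacing)
    if sx.size == 0:
        raise ValueError("scene has no emitting road sources")
    emis = np.array([params.emission_by_type[t] for t in stypes])

    veg = np.isin(np.rint(scene.landcover.values).astype(int), (3, 4, 5, 6))
    veg_frac = ndimage.uniform_filter(veg.astype(float), size=9)
    veg_r = veg_frac.ravel()
    built = scene.building_height.values > 0

    def built_at(px, py):
        row, col = grid.cell_of(px, py)
        ok = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
        out = np.zeros(px.shape, dtype=bool)
        out[ok] = built[row[ok], col[ok]]
        return out

    base = 10.0 * np.log10(params.source_spacing)
    energy = np.zeros(rx.size)
    chunk = 128  # bounds peak memory of the pairwise distance blocks
    for lo in range(0, sx.size, chunk):
        hi = min(lo + chunk, sx.size)
        dx = rx[:, None] - sx[None, lo:hi]
        dy = ry[:, None] - sy[None, lo:hi]
        d = np.hypot(dx, dy)
        dd = np.maximum(d, params.d0)
        L = (emis[None, lo:hi] + base
             - params.spreading_coefficient * np.log10(dd / params.d0)
             - params.ground_absorption * (d / 1000.0) * veg_r[:, None])
        if params.shielding and params.shielding_db != 0.0:
            with np.errstate(invalid="ignore", divide="ignore"):
                f = np.where(d > 0, np.minimum(15.0, d / 2.0) / np.maximum(d, 1e-9), 0.0)
            mx = 0.5 * (rx[:, None] + sx[None, lo:hi])
            my_ = 0.5 * (ry[:, None] + sy[None, lo:hi])
            px = rx[:, None] + f * (sx[None, lo:hi] - rx[:, None])
            py = ry[:, None] + f * (sy[None, lo:hi] - ry[:, None])
            shd = built_at(mx, my_) | built_at(px, py)
            L = L - params.shielding_db * shd
        energy += np.sum(10.0 ** (L / 10.0), axis=1)
    lden = 10.0 * np.log10(energy).reshape(grid.shape)
    return grid.like(lden, units="dB(A)")


def energetic_sum(levels) -> float:
    """Combine sound levels energetically: 10 log10(sum 10^(L/10))."""
    levels = np.asarray(levels, dtype=float)
    return float(10.0 * np.log10(np.sum(10.0 ** (levels / 10.0))))


# ---------------------------------------------------------------------------
# Known-coefficient linear fixture
# ---------------------------------------------------------------------------

def generate_linear_lden(stack, betas, noise_sd: float, seed: int) -> RasterGrid:
    """Lden = intercept + X @ betas[1:] + N(0, noise_sd) per masked cell.

    ``betas`` has length ``stack.width + 1``, intercept first.  Exact
    parameter-recovery fixture: with ``noise_sd = 0`` an OLS fit on all cells
    returns ``betas`` to numerical precision.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.size != stack.width + 1:
        raise ValueError(f"betas length {betas.size} != stack width + 1 "
                         f"({stack.width + 1})")
    rng = np.random.default_rng(seed)
    grid = stack.grid
    X = stack.matrix()
    vals = betas[0] + X @ betas[1:]
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, vals.size)
    out = np.full(grid.shape, grid.nodata)
    rr, cc = np.nonzero(stack.mask)
    out[rr, cc] = vals
    return grid.like(out, units="dB(A)")
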