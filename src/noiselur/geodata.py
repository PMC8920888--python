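"""Georeferenced grid and vector containers plus the 10-m rasterization layer.

Rasters live on a planar metric grid with a top-left origin: row 0 is the
northernmost row and the cell extent of column ``c`` is the half-open interval
``[origin_x + c*cell_size, origin_x + (c+1)*cell_size)``.  All coordinates are
meters in a common (already projected) frame; CRS handling is the caller's
responsibility.

On disk, rasters are single-band ESRI ASCII grids (``.asc``) and vector layers
are GeoJSON FeatureCollections.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon, shape as shapely_shape, mapping

logger = logging.getLogger(__name__)

#: The six functional road types used as traffic-intensity proxies, ordered
#: from loudest to quietest expected emission.
ROAD_TYPES = ("motorway", "trunk", "primary", "secondary", "tertiary", "residential")


@dataclass
class RasterGrid:
    """A single-band georeferenced value grid.

    Parameters
    ----------
    values
        2-D float array, row 0 = northernmost row.
    origin_x, origin_y
        Coordinates (m) of the *top-left corner* of the grid.
    cell_size
        Cell edge length in meters (> 0).
    nodata
        Sentinel for missing cells.
    units
        Free-text units, e.g. ``"dB(A)"``, ``"m"``, ``"%"``.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 10.0
    nodata: float = -9999.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    # -- geometry helpers -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int):
        """(x, y) of cell centers; vectorized over row/col arrays."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_of(self, x, y):
        """(row, col) of the cells containing planar points (half-open extents)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def center_coords(self):
        """Meshgrid arrays (X, Y) of all cell-center coordinates."""
        rows = np.arange(self.n_rows)
        cols = np.arange(self.n_cols)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def like(self, values: np.ndarray, units: str | None = None) -> "RasterGrid":
        """A new grid sharing this grid's geometry."""
        return replace(self, values=np.asarray(values, dtype=float),
                       units=self.units if units is None else units)

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (self.shape == other.shape
                and np.isclose(self.origin_x, other.origin_x)
                and np.isclose(self.origin_y, other.origin_y)
                and np.isclose(self.cell_size, other.cell_size))


@dataclass
class RoadSegment:
    """One typed polyline with its emission-proxy attributes."""

    coords: np.ndarray  # (k, 2) planar meters
    road_type: str
    lanes: int = 1
    tunnel: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.road_type not in ROAD_TYPES:
            raise ValueError(f"unknown road type {self.road_type!r}")
        if self.coords.ndim != 2 or self.coords.shape[0] < 2 or self.coords.shape[1] != 2:
            raise ValueError("segment needs >= 2 planar coordinates")
        self.lanes = int(self.lanes)
        if self.lanes < 1:
            raise ValueError("lanes must be >= 1")

    @property
    def geometry(self) -> LineString:
        return LineString(self.coords)

    @property
    def length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.coords, axis=0).T)))


@dataclass
class RoadNetwork:
    """A collection of typed road segments (the emission proxies)."""

    segments: list[RoadSegment] = field(default_factory=list)

    def of_type(self, road_type: str, include_tunnels: bool = False) -> "RoadNetwork":
        segs = [s for s in self.segments
                if s.road_type == road_type and (include_tunnels or not s.tunnel)]
        return RoadNetwork(segs)

    def emitting(self) -> "RoadNetwork":
        """Non-tunnel segments only; tunnels carry no emission weight."""
        return RoadNetwork([s for s in self.segments if not s.tunnel])

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class Zone:
    id: str
    label: str
    polygon: Polygon


@dataclass
class ZoneSet:
    """Polygons used for spatial blocking or land-use strata."""

    zones: list[Zone]
    kind: str = "admin"  # {"admin", "landuse"}

    def __post_init__(self) -> None:
        ids = [z.id for z in self.zones]
        if len(set(ids)) != len(ids):
            raise ValueError("zone ids must be unique")

    def __len__(self) -> int:
        return len(self.zones)

    @property
    def labels(self) -> list[str]:
        return [z.label for z in self.zones]


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a single-band ESRI ASCII grid with full float64 precision."""
    path = Path(path)
    vals = np.where(grid.valid_mask, grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {grid.origin_y - grid.n_rows * grid.cell_size!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        np.savetxt(fh, vals, fmt="%.17g")


def read_raster(path: str | Path, expected_cell_size: float | None = None,
                units: str = "") -> RasterGrid:
    """Read a single-band ESRI ASCII grid.

    Raises
    ------
    ValueError
        If the header is missing georeference keys, or the cell size differs
        from ``expected_cell_size``.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - set(header)
    if missing:
        raise ValueError(f"raster {path} lacks georeference keys: {sorted(missing)}")
    cell = header["cellsize"]
    if expected_cell_size is not None and not np.isclose(cell, expected_cell_size):
        raise ValueError(
            f"raster {path} has cell size {cell} m, expected {expected_cell_size} m")
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"raster body {values.shape} disagrees with header "
                         f"({nrows}, {ncols})")
    return RasterGrid(
        values=values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        nodata=header.get("nodata_value", -9999.0),
        units=units,
    )


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON)
# ---------------------------------------------------------------------------

#: OSM ``highway`` values mapped into the six-type universe; everything else
#: (service, track, *_link, ...) is dropped.
HIGHWAY_MAP = {t: t for t in ROAD_TYPES}


def read_roads(path: str | Path, highway_map: dict[str, str] | None = None) -> RoadNetwork:
    """Read a GeoJSON line layer with OSM-style ``highway`` tags.

    Features whose ``highway`` value is not in the map are dropped (count
    logged); features without a ``highway`` property are skipped with a
    warning; ``lanes`` defaults to 1; ``tunnel`` is truthy when the property
    is ``yes``/``true``/``1``.
    """
    highway_map = HIGHWAY_MAP if highway_map is None else highway_map
    with open(path) as fh:
        gj = json.load(fh)
    segments: list[RoadSegment] = []
    dropped = 0
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        highway = props.get("highway")
        if highway is None:
            logger.warning("road feature without 'highway' property skipped")
            continue
        road_type = highway_map.get(str(highway))
        if road_type is None:
            dropped += 1
            continue
        geom = shapely_shape(feat["geometry"])
        if geom.geom_type == "LineString":
            lines = [geom]
        elif geom.geom_type == "MultiLineString":
            lines = list(geom.geoms)
        else:
            raise ValueError(f"road feature has non-line geometry {geom.geom_type}")
        lanes = props.get("lanes")
        lanes = 1 if lanes in (None, "") else int(lanes)
        tunnel = str(props.get("tunnel", "")).lower() in ("yes", "true", "1")
        for line in lines:
            segments.append(RoadSegment(np.asarray(line.coords), road_type,
                                        lanes=lanes, tunnel=tunnel))
    if dropped:
        logger.info("dropped %d road features with unmapped highway values", dropped)
    return RoadNetwork(segments)


def write_roads(roads: RoadNetwork, path: str | Path) -> None:
    feats = []
    for seg in roads.segments:
        feats.append({
            "type": "Feature",
            "geometry": mapping(seg.geometry),
            "properties": {
                "highway": seg.road_type,
                "lanes": seg.lanes,
                "tunnel": "yes" if seg.tunnel else "no",
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_zones(path: str | Path, kind: str = "admin") -> ZoneSet:
    with open(path) as fh:
        gj = json.load(fh)
    zones = []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        geom = shapely_shape(feat["geometry"])
        zones.append(Zone(id=str(props.get("id", i)),
                          label=str(props.get("label", props.get("id", i))),
                          polygon=geom))
    return ZoneSet(zones, kind=kind)


def write_zones(zones: ZoneSet, path: str | Path) -> None:
    feats = [{
        "type": "Feature",
        "geometry": mapping(z.polygon),
        "properties": {"id": z.id, "label": z.label},
    } for z in zones.zones]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _split_piece_lengths(p0, p1, grid: RasterGrid):
    """Exact clipping of one 2-point piece against the grid lines.

    Yields ((row, col), in-cell length) for each traversed cell; parts outside
    the grid are discarded.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    total = float(np.hypot(*d))
    if total == 0.0:
        return
    cs = grid.cell_size
    ts = [0.0, 1.0]
    # crossings with vertical grid lines x = origin_x + j*cs
    if d[0] != 0.0:
        j0 = int(np.ceil((min(p0[0], p1[0]) - grid.origin_x) / cs))
        j1 = int(np.floor((max(p0[0], p1[0]) - grid.origin_x) / cs))
        for j in range(j0, j1 + 1):
            t = (grid.origin_x + j * cs - p0[0]) / d[0]
            if 0.0 < t < 1.0:
                ts.append(t)
    # crossings with horizontal grid lines y = origin_y - i*cs
    if d[1] != 0.0:
        i0 = int(np.ceil((grid.origin_y - max(p0[1], p1[1])) / cs))
        i1 = int(np.floor((grid.origin_y - min(p0[1], p1[1])) / cs))
        for i in range(i0, i1 + 1):
            t = (grid.origin_y - i * cs - p0[1]) / d[1]
            if 0.0 < t < 1.0:
                ts.append(t)
    ts = sorted(set(ts))
    for ta, tb in zip(ts[:-1], ts[1:]):
        mid = p0 + 0.5 * (ta + tb) * d
        row, col = grid.cell_of(mid[0], mid[1])
        if 0 <= row < grid.n_rows and 0 <= col < grid.n_cols:
            yield (int(row), int(col)), (tb - ta) * total


def rasterize_road_length(roads: RoadNetwork, grid: RasterGrid,
                          road_type: str) -> RasterGrid:
    """Lane-weighted in-cell road length (m) per cell for one road type.

    Each cell's value is the exact clipped length of every non-tunnel segment
    of ``road_type`` inside the cell, multiplied by the segment's lane count.
    Tunnels contribute nothing.  An empty network yields an all-zero raster.
    """
    if road_type not in ROAD_TYPES:
        raise ValueError(f"unknown road type {road_type!r}")
    out = np.zeros(grid.shape)
    for seg in roads.of_type(road_type).segments:
        for a, b in zip(seg.coords[:-1], seg.coords[1:]):
            for (row, col), ln in _split_piece_lengths(a, b, grid):
                out[row, col] += ln * seg.lanes
    return grid.like(out, units="m")


def rasterize_zones(zones: ZoneSet, grid: RasterGrid, by: str = "index") -> RasterGrid:
    """Label each cell by the zone containing its center.

    ``by="index"`` labels with the zone's position in the ZoneSet (0-based);
    ``by="label"`` labels with the index of the zone's *label* in the sorted
    unique label list (useful when several polygons share a settlement class).
    Uncovered cells get the grid's nodata.  Overlapping polygons (two zones
    claiming the same cell center) raise, because blocking would be ambiguous.
    """
    X, Y = grid.center_coords()
    out = np.full(grid.shape, grid.nodata)
    claimed = np.zeros(grid.shape, dtype=bool)
    if by == "label":
        uniq = sorted(set(zones.labels))
        code = {lab: i for i, lab in enumerate(uniq)}
    for idx, zone in enumerate(zones.zones):
        inside = shapely.contains_xy(zone.polygon, X, Y)
        if np.any(inside & claimed):
            raise ValueError(
                f"zone {zone.id!r} overlaps another zone: ambiguous blocking")
        claimed |= inside
        out[inside] = code[zone.label] if by == "label" else idx
    return grid.like(out, units="zone")
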