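"""Focal statistics, proximity, TPI and land-cover fractions against
independent brute-force oracles."""

import numpy as np
import pytest

import noiselur as nl
from noiselur.features import _circular_kernel
from noiselur.geodata import RoadNetwork, RoadSegment


def _brute_focal(values, mask, radius, cell_size, stat):
    """Direct double-loop moving-window oracle."""
    n, m = values.shape
    out = np.zeros((n, m))
    r_cells = int(radius // cell_size) + 1
    for i in range(n):
        for j in range(m):
            acc, cnt = 0.0, 0
            for di in range(-r_cells, r_cells + 1):
                for dj in range(-r_cells, r_cells + 1):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < n and 0 <= jj < m):
                        continue
                    if (di * di + dj * dj) * cell_size ** 2 > radius ** 2 + 1e-9:
                        continue
                    if mask[ii, jj]:
                        acc += values[ii, jj]
                        cnt += 1
            out[i, j] = acc if stat == "sum" else (acc / cnt if cnt else np.nan)
    return out


# ---------------------------------------------------------------------------
# Proximity
# ---------------------------------------------------------------------------

def test_proximity_on_road_is_zero(flat_grid):
    # road through the center of cell (0, 0): distance 0 -> log10(1) = 0
    net = RoadNetwork([RoadSegment([[0, 95], [100, 95]], "primary")])
    out = nl.proximity_feature(net, flat_grid, "primary")
    assert out.values[0, 0] == pytest.approx(0.0)


def test_proximity_99m_gives_exactly_two(flat_grid):
    # cell center (5, 95); road passing vertically at x = 104 -> d = 99 m
    net = RoadNetwork([RoadSegment([[104, -100], [104, 300]], "motorway")])
    out = nl.proximity_feature(net, flat_grid, "motorway")
    assert out.values[0, 0] == pytest.approx(np.log10(100.0), abs=1e-12)


def test_proximity_matches_per_segment_brute_force(flat_grid):
    rng = np.random.default_rng(12)
    segs = [RoadSegment(rng.uniform(-20, 120, size=(3, 2)), "tertiary")
            for _ in range(6)]
    net = RoadNetwork(segs)
    out = nl.proximity_feature(net, flat_grid, "tertiary")
    X, Y = flat_grid.center_coords()
    from shapely.geometry import Point
    for i in range(0, 10, 3):
        for j in range(0, 10, 3):
            p = Point(X[i, j], Y[i, j])
            d = min(s.geometry.distance(p) for s in segs)
            assert out.values[i, j] == pytest.approx(np.log10(d + 1), abs=1e-9)


def test_proximity_monotone_under_network_growth(flat_grid):
    net1 = RoadNetwork([RoadSegment([[0, 0], [100, 0]], "primary")])
    net2 = RoadNetwork(net1.segments
                       + [RoadSegment([[0, 50], [100, 50]], "primary")])
    d1 = nl.proximity_feature(net1, flat_grid, "primary").values
    d2 = nl.proximity_feature(net2, flat_grid, "primary").values
    assert np.all(d2 <= d1 + 1e-12)


def test_proximity_empty_network_sentinel(flat_grid, caplog):
    out = nl.proximity_feature(RoadNetwork([]), flat_grid, "trunk")
    assert np.ptp(out.values) == 0  # constant sentinel column


# ---------------------------------------------------------------------------
# Focal statistics
# ---------------------------------------------------------------------------

def test_focal_mean_of_constant_is_constant(flat_grid):
    grid = flat_grid.like(np.full((10, 10), 4.2))
    for radius in (12.5, 50.0, 200.0):
        out = nl.focal_statistic(grid, radius, "mean")
        np.testing.assert_allclose(out.values, 4.2, atol=1e-9)


def test_radius_12p5_window_is_rook_neighborhood(flat_grid):
    """On a 10-m grid a 12.5-m radius covers the focal cell + 4 rook
    neighbors (10 <= 12.5 < 14.14)."""
    kernel = _circular_kernel(12.5, 10.0)
    expected = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=float)
    np.testing.assert_array_equal(kernel, expected)
    onehot = np.zeros((10, 10))
    onehot[5, 5] = 1.0
    out = nl.focal_statistic(flat_grid.like(onehot), 12.5, "sum")
    assert out.values[5, 5] == pytest.approx(1.0)
    assert out.values.sum() == pytest.approx(5.0)  # hot cell seen by 5 windows


def test_focal_mean_edge_normalization(flat_grid):
    """Corner cells divide by the in-domain window count, not the full
    window size."""
    grid = flat_grid.like(np.ones((10, 10)))
    out = nl.focal_statistic(grid, 12.5, "mean")
    assert out.values[0, 0] == pytest.approx(1.0)  # 3 cells in, divisor 3


@pytest.mark.parametrize("stat", ["sum", "mean"])
@pytest.mark.parametrize("radius", [12.5, 25.0, 50.0])
def test_focal_matches_brute_force(flat_grid, stat, radius):
    rng = np.random.default_rng(5)
    vals = rng.normal(size=(10, 10))
    mask = rng.random((10, 10)) > 0.15
    grid = nl.RasterGrid(np.where(mask, vals, -9999.0), origin_y=100.0)
    out = nl.focal_statistic(grid, radius, stat)
    expected = _brute_focal(vals, mask, radius, 10.0, stat)
    np.testing.assert_allclose(out.values, expected, atol=1e-9)


def test_window_membership_symmetry():
    kernel = _circular_kernel(50.0, 10.0)
    np.testing.assert_array_equal(kernel, kernel[::-1, ::-1])
    np.testing.assert_array_equal(kernel, kernel.T)


# ---------------------------------------------------------------------------
# TPI
# ---------------------------------------------------------------------------

def test_tpi_flat_raster_is_zero(flat_grid):
    grid = flat_grid.like(np.full((10, 10), 123.0))
    out = nl.tpi(grid, 50.0)
    np.testing.assert_allclose(out.values, 0.0, atol=1e-9)


def test_tpi_tower_is_positive(flat_grid):
    vals = np.zeros((10, 10))
    vals[5, 5] = 10.0
    out = nl.tpi(flat_grid.like(vals), 12.5)
    assert out.values[5, 5] == pytest.approx(10.0)  # center minus zero mean
    assert out.values[5, 6] < 0                      # neighbor looks lower


def test_tpi_matches_brute_force():
    rng = np.random.default_rng(8)
    vals = rng.normal(size=(30, 30)) * 5
    grid = nl.RasterGrid(vals, origin_y=300.0)
    out = nl.tpi(grid, 25.0)
    kernel = _circular_kernel(25.0, 10.0)
    r = kernel.shape[0] // 2
    for i in range(0, 30, 7):
        for j in range(0, 30, 7):
            acc, cnt = 0.0, 0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if (di == 0 and dj == 0) or not (0 <= ii < 30 and 0 <= jj < 30):
                        continue
                    if kernel[di + r, dj + r]:
                        acc += vals[ii, jj]
                        cnt += 1
            assert out.values[i, j] == pytest.approx(vals[i, j] - acc / cnt,
                                                     abs=1e-9)


# ---------------------------------------------------------------------------
# Land-cover fractions
# ---------------------------------------------------------------------------

def test_uniform_class_gives_100(flat_grid):
    grid = flat_grid.like(np.full((10, 10), 3.0))
    assert np.all(nl.landcover_fraction(grid, 3, 100.0).values == 100.0)
    assert np.all(nl.landcover_fraction(grid, 5, 100.0).values == 0.0)


def test_fractions_partition_to_100(scene150):
    total = np.zeros(scene150.landcover.shape)
    for cid in nl.LANDCOVER_CLASSES:
        total += nl.landcover_fraction(scene150.landcover, cid, 200.0).values
    np.testing.assert_allclose(total, 100.0, atol=1e-9)


def test_checkerboard_half_and_half(flat_grid):
    vals = np.indices((10, 10)).sum(axis=0) % 2 + 1.0  # classes 1 / 2
    grid = flat_grid.like(vals)
    out = nl.landcover_fraction(grid, 1, 200.0)
    # radius 200 covers the whole 100-m grid from every cell: global share
    expected = 100.0 * np.mean(vals == 1)
    np.testing.assert_allclose(out.values, expected, atol=1e-9)


def test_unknown_class_rejected(flat_grid):
    with pytest.raises(ValueError, match="class"):
        nl.landcover_fraction(flat_grid, 9, 100.0)


# ---------------------------------------------------------------------------
# Candidate stack and road-type diagnostics
# ---------------------------------------------------------------------------

def test_candidate_stack_has_126_columns(stack150):
    assert stack150.width == 6 + 15 * 8 == 126
    proximity = [s for s in stack150.specs if s.radius is None]
    assert len(proximity) == 6
    radii_per_var = {}
    for s in stack150.specs:
        if s.radius is not None:
            radii_per_var.setdefault(s.variable, set()).add(s.radius)
    assert len(radii_per_var) == 15
    assert all(v == set(nl.RADII) for v in radii_per_var.values())


def test_stack_has_no_missing_values_inside_mask(stack150):
    M = stack150.matrix()
    assert np.all(np.isfinite(M))


def test_stack_roundtrip_dir(tmp_path, stack150):
    sub = stack150.select(stack150.names[:4])
    sub.to_dir(tmp_path / "stack")
    back = nl.FeatureStack.from_dir(tmp_path / "stack")
    assert back.names == sub.names
    np.testing.assert_allclose(back.columns[sub.names[0]],
                               sub.columns[sub.names[0]], atol=1e-12)


def test_missing_scene_layer_named_in_error(scene150):
    class Partial:
        dem = scene150.dem
        building_height = scene150.building_height
        landcover = None
        roads = scene150.roads
    with pytest.raises(ValueError, match="landcover"):
        nl.build_feature_stack(Partial())


def test_anova_hand_computed_three_groups(flat_grid):
    """One-way ANOVA F matches textbook sums-of-squares on a 9-value toy."""
    lden_vals = np.full((10, 10), np.nan)
    groups = {"primary": [1.0, 2.0, 3.0], "secondary": [2.0, 3.0, 4.0],
              "tertiary": [6.0, 7.0, 8.0]}
    segs, col = [], 0
    for t, vals in groups.items():
        for v in vals:
            lden_vals[0, col] = v
            x0 = col * 10
            segs.append(RoadSegment([[x0 + 2, 95], [x0 + 8, 95]], t))
            col += 1
    lden_vals[np.isnan(lden_vals)] = -9999.0
    lden = nl.RasterGrid(lden_vals, origin_y=100.0)
    _, f_stat, p = nl.road_type_summary(lden, RoadNetwork(segs))
    # hand arithmetic: grand mean 4, SSB = 3*((2-4)^2+(3-4)^2+(7-4)^2) = 42,
    # SSW = 6, F = (42/2)/(6/6) = 21
    assert f_stat == pytest.approx(21.0, abs=1e-9)
    from scipy import stats as sps
    assert p == pytest.approx(1 - sps.f.cdf(21.0, 2, 6), abs=1e-12)


def test_anova_identical_groups_f_zero(flat_grid):
    vals = np.full((10, 10), 50.0)
    lden = flat_grid.like(vals)
    segs = [RoadSegment([[0, 95 - 10 * i], [100, 95 - 10 * i]], t)
            for i, t in enumerate(nl.ROAD_TYPES)]
    _, f_stat, p = nl.road_type_summary(lden, RoadNetwork(segs))
    assert f_stat == 0.0 and p == 1.0


def test_anova_separated_groups_significant(flat_grid):
    rng = np.random.default_rng(0)
    vals = np.zeros((10, 10))
    vals[0, :] = 50 + 0.1 * rng.standard_normal(10)
    vals[5, :] = 80 + 0.1 * rng.standard_normal(10)
    lden = flat_grid.like(vals)
    net = RoadNetwork([RoadSegment([[0, 95], [100, 95]], "residential"),
                       RoadSegment([[0, 45], [100, 45]], "motorway")])
    _, _, p = nl.road_type_summary(lden, net)
    assert p < 0.001


def test_lden_proximity_negatively_correlated(lden150, stack150):
    """Sanity direction: closer to motorways (small log-proximity) is louder."""
    prox = stack150.columns["motorway_proximity"]
    r = np.corrcoef(prox.ravel(), lden150.values.ravel())[0, 1]
    assert r < 0
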