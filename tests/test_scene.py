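"""Synthetic scenes and the two reference-Lden fixtures."""

import numpy as np
import pytest

import noiselur as nl
from noiselur.geodata import RoadNetwork, RoadSegment
from noiselur.scene import Scene, _point_sources


def _segments_equal(a, b):
    return (a.road_type == b.road_type and a.lanes == b.lanes
            and a.tunnel == b.tunnel and np.array_equal(a.coords, b.coords))


def test_scene_determinism():
    s1 = nl.generate_scene(seed=5, n_rows=60, n_cols=60)
    s2 = nl.generate_scene(seed=5, n_rows=60, n_cols=60)
    np.testing.assert_array_equal(s1.dem.values, s2.dem.values)
    np.testing.assert_array_equal(s1.building_height.values,
                                  s2.building_height.values)
    np.testing.assert_array_equal(s1.landcover.values, s2.landcover.values)
    assert all(_segments_equal(a, b)
               for a, b in zip(s1.roads.segments, s2.roads.segments))


def test_different_seeds_differ():
    s1 = nl.generate_scene(seed=1, n_rows=60, n_cols=60)
    s2 = nl.generate_scene(seed=2, n_rows=60, n_cols=60)
    assert not np.array_equal(s1.dem.values, s2.dem.values)
    assert not all(_segments_equal(a, b)
                   for a, b in zip(s1.roads.segments, s2.roads.segments))


def test_too_small_scene_rejected():
    with pytest.raises(ValueError, match="50"):
        nl.generate_scene(seed=1, n_rows=40, n_cols=200)


def test_scene_completeness_at_300():
    scene = nl.generate_scene(seed=11, n_rows=300, n_cols=300)
    types = {s.road_type for s in scene.roads.segments}
    assert types == set(nl.ROAD_TYPES)
    assert len(scene.admin_zones) >= 6
    assert len(scene.landuse_zones) >= 4
    labels = nl.rasterize_zones(scene.admin_zones, scene.grid)
    assert labels.valid_mask.mean() >= 0.95
    lc = scene.landcover.values
    assert np.all((lc >= 1) & (lc <= 7))  # every cell exactly one class
    assert np.any(scene.building_height.values > 0)


def test_scene_roundtrip(tmp_path, scene150):
    from noiselur.scene import load_scene, save_scene
    save_scene(scene150, tmp_path / "scene")
    back = load_scene(tmp_path / "scene")
    np.testing.assert_array_equal(back.dem.values, scene150.dem.values)
    np.testing.assert_array_equal(back.landcover.values,
                                  scene150.landcover.values)
    assert len(back.roads) == len(scene150.roads)
    assert back.landuse_zones.labels == scene150.landuse_zones.labels


# ---------------------------------------------------------------------------
# Acoustic fixture
# ---------------------------------------------------------------------------

def test_energetic_sum_examples():
    # duplicating a source raises the total by 10 log10(2) ~ 3.0103 dB
    assert nl.energetic_sum([60.0, 60.0]) == pytest.approx(
        60.0 + 10 * np.log10(2), abs=1e-9)
    # permutation invariance
    assert nl.energetic_sum([50, 60, 70]) == pytest.approx(
        nl.energetic_sum([70, 50, 60]), abs=1e-12)
    # monotone: adding a source never lowers the total
    assert nl.energetic_sum([60, 40]) > nl.energetic_sum([60.0])


def test_single_source_level_at_reference_distance():
    """One isolated point source: the cell at distance d0 sees exactly the
    single-source level E + 10 log10(spacing)."""
    params = nl.AcousticParams(ground_absorption=0.0, shielding=False,
                               source_spacing=5.0)
    # a 5-m stub at 5-m spacing produces exactly one source at its midpoint
    scene = nl.generate_scene(seed=3, n_rows=50, n_cols=50)
    cx, cy = scene.grid.cell_center(25, 25)  # put source on a cell center
    scene = Scene(dem=scene.dem, building_height=scene.building_height,
                  landcover=scene.landcover,
                  roads=RoadNetwork([RoadSegment([[cx - 2.5, cy], [cx + 2.5, cy]],
                                                 "motorway")]),
                  admin_zones=scene.admin_zones,
                  landuse_zones=scene.landuse_zones, seed=3)
    xs, ys, types = _point_sources(scene.roads, params.source_spacing)
    assert len(xs) == 1 and np.isclose(xs[0], cx) and np.isclose(ys[0], cy)
    lden = nl.simulate_lden(scene, params)
    expected = params.emission_by_type["motorway"] + 10 * np.log10(5.0)
    # receiver cell center is the source position: d = 0 -> clamped to d0
    assert lden.values[25, 25] == pytest.approx(expected, abs=1e-9)
    # doubling distance drops the level by spreading*log10(2) ~ 6.0206 dB
    d1 = lden.values[25, 27]   # 20 m
    d2 = lden.values[25, 29]   # 40 m
    assert d1 - d2 == pytest.approx(20 * np.log10(2), abs=1e-9)


def test_monotone_decay_along_transect():
    """A single straight road: levels strictly decrease with perpendicular
    distance beyond d0."""
    scene = nl.generate_scene(seed=3, n_rows=60, n_cols=60)
    road = RoadNetwork([RoadSegment([[5, 305], [595, 305]], "primary")])
    scene = Scene(dem=scene.dem, building_height=scene.grid.like(np.zeros((60, 60))),
                  landcover=scene.landcover, roads=road,
                  admin_zones=scene.admin_zones,
                  landuse_zones=scene.landuse_zones, seed=3)
    lden = nl.simulate_lden(scene, nl.AcousticParams(ground_absorption=0.0,
                                                     shielding=False))
    transect = lden.values[30:, 30]  # walking south, away from the road
    assert np.all(np.diff(transect) < 0)


def test_adding_sources_never_lowers_levels():
    """Energetic monotonicity: adding a road raises (or keeps) every cell."""
    base = nl.generate_scene(seed=9, n_rows=60, n_cols=60)
    one_road = RoadNetwork(base.roads.segments[:4])
    two_roads = RoadNetwork(base.roads.segments[:6])

    def with_roads(net):
        return Scene(dem=base.dem, building_height=base.building_height,
                     landcover=base.landcover, roads=net,
                     admin_zones=base.admin_zones,
                     landuse_zones=base.landuse_zones, seed=9)

    la = nl.simulate_lden(with_roads(one_road))
    lb = nl.simulate_lden(with_roads(two_roads))
    assert np.all(lb.values >= la.values - 1e-9)


def test_on_road_emission_hierarchy(lden150, scene150):
    """Per-type on-road mean Lden preserves the emission ordering
    motorway > trunk > primary > secondary > tertiary > residential."""
    summary, f_stat, p = nl.road_type_summary(lden150, scene150.roads)
    means = summary.loc[list(nl.ROAD_TYPES), "mean"].to_numpy()
    assert np.all(np.diff(means) < 0)
    assert p < 0.001


def test_emission_ordering_validated():
    with pytest.raises(ValueError, match="ordered"):
        nl.AcousticParams(emission_by_type={
            "motorway": 60, "trunk": 76, "primary": 73,
            "secondary": 68, "tertiary": 60, "residential": 51})


# ---------------------------------------------------------------------------
# Known-coefficient linear fixture
# ---------------------------------------------------------------------------

def test_linear_fixture_exact_recovery(stack150):
    sub = stack150.select(stack150.names[:5])
    betas = np.array([40.0, -3.0, 1.5, 0.2, -0.7, 2.0])
    lden = nl.generate_linear_lden(sub, betas, noise_sd=0.0, seed=1)
    rr, cc = np.nonzero(sub.mask)
    fit = nl.fit_ols(sub.matrix(rr, cc), lden.values[rr, cc],
                     feature_names=sub.names)
    np.testing.assert_allclose(fit.params, betas, rtol=1e-8, atol=1e-8)
    assert fit.metrics.r2 == pytest.approx(1.0)


def test_linear_fixture_single_cell_dot_product(stack150):
    sub = stack150.select(stack150.names[:3])
    betas = np.array([10.0, 2.0, -1.0, 0.5])
    lden = nl.generate_linear_lden(sub, betas, noise_sd=0.0, seed=0)
    r, c = 40, 60
    x = [sub.columns[n][r, c] for n in sub.names]
    expected = 10.0 + 2.0 * x[0] - 1.0 * x[1] + 0.5 * x[2]
    assert lden.values[r, c] == pytest.approx(expected, abs=1e-10)


def test_linear_fixture_dimension_mismatch(stack150):
    sub = stack150.select(stack150.names[:3])
    with pytest.raises(ValueError, match="length"):
        nl.generate_linear_lden(sub, [1.0, 2.0], noise_sd=0.0, seed=0)
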