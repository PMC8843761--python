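import math

import numpy as np
import pytest
import shapely
from shapely.geometry import LineString, Point

from kernelscape.covariates import (WindowMetricSpec, build_multiscale_stack,
                                    circular_footprint, distance_to_features,
                                    feature_density, focal_mean,
                                    terrain_derivatives, trasp, window_metric)
from kernelscape.raster import RasterGrid

from conftest import make_grid


# ----------------------------------------------------------------------
# terrain derivatives
# ----------------------------------------------------------------------
class TestTerrainDerivatives:
    def test_flat_dem_has_zero_relief_metrics(self):
        dem = make_grid(np.full((8, 8), 1500.0), cell_size=250.0)
        slope, asp, tri, slp = terrain_derivatives(dem)
        assert np.allclose(slope.values, 0.0)
        assert np.allclose(tri.values, 0.0)
        assert np.allclose(slp.values, 0.0)
        assert np.allclose(asp.values, 0.5)  # undefined aspect -> neutral

    def test_trasp_analytic_endpoints(self):
        assert trasp(30.0) == pytest.approx(0.0, abs=1e-12)
        assert trasp(210.0) == pytest.approx(1.0, abs=1e-12)
        assert trasp(120.0) == pytest.approx(0.5, abs=1e-12)

    def test_inclined_plane_slope_closed_form(self):
        # 1 m rise per cell eastward
        cs = 250.0
        cols = np.arange(12, dtype=float)
        dem = make_grid(np.tile(cols, (12, 1)), cell_size=cs)
        slope, _, _, _ = terrain_derivatives(dem)
        expected = math.degrees(math.atan(1.0 / cs))
        assert np.allclose(slope.values[1:-1, 1:-1], expected, atol=1e-9)

    def test_tiny_dem_rejected(self):
        with pytest.raises(ValueError):
            terrain_derivatives(make_grid(np.zeros((2, 2))))


# ----------------------------------------------------------------------
# focal mean
# ----------------------------------------------------------------------
class TestFocalMean:
    def test_constant_raster_unchanged(self):
        g = make_grid(np.full((15, 15), 7.5), cell_size=10.0)
        out = focal_mean(g, 35.0)
        assert np.allclose(out.values, 7.5)

    def test_delta_mass_conservation(self):
        vals = np.zeros((21, 21))
        vals[10, 10] = 1.0
        g = make_grid(vals, cell_size=1.0)
        out = focal_mean(g, 2.0)
        foot = circular_footprint(2.0, 1.0)
        k = int(foot.sum())  # interior window size
        covered = out.values[8:13, 8:13][foot]
        assert np.allclose(covered, 1.0 / k)
        assert out.values[0, 0] == 0.0

    def test_matches_brute_force_with_nodata(self, rng):
        vals = rng.normal(size=(20, 20))
        vals[rng.random((20, 20)) < 0.1] = np.nan
        g = make_grid(vals, cell_size=1.0)
        radius = 3.2
        out = focal_mean(g, radius)
        for r in range(20):
            for c in range(20):
                if np.isnan(vals[r, c]):
                    assert np.isnan(out.values[r, c])
                    continue
                acc, n = 0.0, 0
                for rr in range(20):
                    for cc in range(20):
                        if (rr - r) ** 2 + (cc - c) ** 2 <= radius ** 2 + 1e-9 \
                                and not np.isnan(vals[rr, cc]):
                            acc += vals[rr, cc]
                            n += 1
                assert out.values[r, c] == pytest.approx(acc / n, abs=1e-9)

    def test_sub_cell_radius_is_identity_with_warning(self):
        g = make_grid(np.arange(16.0).reshape(4, 4), cell_size=10.0)
        with pytest.warns(UserWarning):
            out = focal_mean(g, 1.0)
        assert np.allclose(out.values, g.values)


# ----------------------------------------------------------------------
# moving-window landscape metrics
# ----------------------------------------------------------------------
def two_patch_fixture():
    """7x7 two-class map: a 2x2 and a 1x2 patch of class 1 in class 0."""
    lc = np.zeros((7, 7))
    lc[1:3, 1:3] = 1.0
    lc[4:6, 4] = 1.0
    return make_grid(lc, cell_size=1.0)


class TestWindowMetrics:
    def test_single_class_window(self):
        g = make_grid(np.zeros((7, 7)), cell_size=1.0)
        center = (3, 3)
        radius = 5.0  # covers the whole 7x7 from the center
        vals = {}
        for metric in ("PLAND", "SHDI", "ED", "PD"):
            spec = (WindowMetricSpec(metric, radius, "class", 0)
                    if metric == "PLAND" else WindowMetricSpec(metric, radius))
            vals[metric] = window_metric(g, spec).values[center]
        assert vals["PLAND"] == pytest.approx(100.0)
        assert vals["SHDI"] == pytest.approx(0.0)
        assert vals["ED"] == pytest.approx(0.0)
        # one patch over 49 m^2 = 49e-4 ha -> patches per 100 ha
        assert vals["PD"] == pytest.approx(1.0 / 49e-4 * 100.0)

    def test_equal_two_class_shdi_is_ln2(self):
        lc = np.zeros((6, 6))
        lc[:, 3:] = 1.0
        g = make_grid(lc, cell_size=1.0)
        out = window_metric(g, WindowMetricSpec("SHDI", 10.0))
        assert out.values[2, 2] == pytest.approx(math.log(2.0), abs=1e-12)

    def test_hand_computed_two_patch_fixture(self):
        g = two_patch_fixture()
        center = (3, 3)
        radius = 5.0
        n = 49
        area_ha = n * 1.0 / 1e4
        # hand counts: class-1 patches of 4 and 2 cells; class 0 one patch;
        # 14 boundary edges; class-1 like-adjacencies 5, class-0 65
        pland = window_metric(
            g, WindowMetricSpec("PLAND", radius, "class", 1)).values[center]
        lpi = window_metric(
            g, WindowMetricSpec("LPI", radius, "class", 1)).values[center]
        pd_ = window_metric(g, WindowMetricSpec("PD", radius)).values[center]
        ed = window_metric(g, WindowMetricSpec("ED", radius)).values[center]
        shdi = window_metric(g, WindowMetricSpec("SHDI", radius)).values[center]
        ai = window_metric(g, WindowMetricSpec("AI", radius)).values[center]
        assert pland == pytest.approx(100.0 * 6 / 49)
        assert lpi == pytest.approx(100.0 * 4 / 49)
        assert pd_ == pytest.approx(3 / area_ha * 100.0)
        assert ed == pytest.approx(14.0 / area_ha)
        p0, p1 = 43 / 49, 6 / 49
        assert shdi == pytest.approx(-(p0 * math.log(p0) + p1 * math.log(p1)))
        # max like-adjacencies: 43 cells -> 72; 6 cells -> 7
        assert ai == pytest.approx(100.0 * (p0 * 65 / 72 + p1 * 5 / 7))

    def test_label_permutation_invariance(self, rng):
        lc = rng.integers(0, 3, size=(12, 12)).astype(float)
        g = make_grid(lc, cell_size=1.0)
        relabeled = make_grid((lc + 1) % 3, cell_size=1.0)
        for metric in ("SHDI", "PD", "ED", "AI"):
            a = window_metric(g, WindowMetricSpec(metric, 3.0)).values
            b = window_metric(relabeled, WindowMetricSpec(metric, 3.0)).values
            assert np.allclose(a, b, equal_nan=True)

    def test_unknown_class_code_rejected(self):
        g = make_grid(np.full((5, 5), 9.0))
        with pytest.raises(ValueError):
            window_metric(g, WindowMetricSpec("SHDI", 2.0),
                          valid_classes=range(7))

    def test_pland_converges_to_landscape_proportion(self):
        g = two_patch_fixture()
        spec_small = WindowMetricSpec("PLAND", 1.5, "class", 1)
        spec_big = WindowMetricSpec("PLAND", 50.0, "class", 1)
        big = window_metric(g, spec_big).values
        assert np.allclose(big, 100.0 * 6 / 49)
        small = window_metric(g, spec_small).values
        assert not np.allclose(small, big)


# ----------------------------------------------------------------------
# distances and densities
# ----------------------------------------------------------------------
class TestFeatureLayers:
    def test_single_point_distance_closed_form(self, unit_grid):
        pt = Point(5.0, 5.0)
        out = distance_to_features([pt], unit_grid)
        X, Y = unit_grid.cell_centers()
        expected = np.hypot(X - 5.0, Y - 5.0)
        assert np.allclose(out.values, expected, atol=1e-9)
        r, c = unit_grid.index(5.0, 5.0)
        assert out.values[r, c] <= math.sqrt(2) / 2

    def test_distance_matches_brute_force_scan(self, rng, unit_grid):
        pts = [Point(xy) for xy in rng.uniform(0, 10, size=(6, 2))]
        out = distance_to_features(pts, unit_grid)
        X, Y = unit_grid.cell_centers()
        brute = np.min([np.hypot(X - p.x, Y - p.y) for p in pts], axis=0)
        assert np.allclose(out.values, brute, atol=1e-9)

    def test_empty_feature_set_rejected(self, unit_grid):
        with pytest.raises(ValueError):
            distance_to_features([], unit_grid)

    def test_point_density_analytic(self, unit_grid):
        out = feature_density([Point(4.5, 4.5)], radius=2.0,
                              grid_template=unit_grid)
        r, c = unit_grid.index(4.5, 4.5)
        area_km2 = math.pi * (2.0 / 1000.0) ** 2
        assert out.values[r, c] == pytest.approx(1.0 / area_km2)

    def test_no_features_zero_raster(self, unit_grid):
        out = feature_density([], radius=2.0, grid_template=unit_grid)
        assert np.allclose(out.values, 0.0)

    def test_road_chord_length(self):
        grid = RasterGrid(np.zeros((41, 41)), cell_size=1.0,
                          origin=(0.0, 41.0))
        road = LineString([(-100, 20.5), (200, 20.5)])
        radius = 5.0
        out = feature_density([road], radius, grid)
        r, c = grid.index(20.5, 20.5)
        chord_km = 2 * radius / 1000.0
        area_km2 = math.pi * (radius / 1000.0) ** 2
        assert out.values[r, c] == pytest.approx(chord_km / area_km2, rel=0.05)


# ----------------------------------------------------------------------
# stack assembly
# ----------------------------------------------------------------------
class TestMultiscaleStack:
    @pytest.fixture()
    def base_layers(self, rng):
        n = 30
        cs = 250.0
        dem = RasterGrid(2000 + 100 * rng.normal(size=(n, n)), cs, (0, n * cs))
        slope, asp, tri, slp = terrain_derivatives(dem)
        lc = RasterGrid(rng.integers(0, 7, (n, n)).astype(float), cs,
                        (0, n * cs))
        return {
            "ELE": dem, "SLP": slp, "ASP": asp, "TRI": tri,
            "NPP": dem.like(rng.random((n, n))),
            "BAM": dem.like((rng.random((n, n)) > 0.5).astype(float)),
            "LANDCOVER": lc,
            "villages": [Point(rng.uniform(0, n * cs), rng.uniform(0, n * cs))
                         for _ in range(5)],
            "roads_major": [LineString([(0, 1000), (n * cs, 1500)])],
            "roads_minor": [LineString([(2000, 0), (2500, n * cs)])],
        }

    def test_full_vocabulary_layer_count(self, base_layers):
        # 16 scalable variables (6 continuous, 4 landscape metrics,
        # 4 class metrics, 2 densities) x 2 scales + 3 distance layers
        stack = build_multiscale_stack(
            base_layers, scales=(1000, 2000),
            landcover_classes={"CBF": 3, "CNF": 4})
        assert len(stack) == 16 * 2 + 3
        assert "Disvil" in stack and "Dismajor" in stack
        assert "LPI_CNF_1000" in stack and "Densrd_2000" in stack

    def test_single_scale_each_variable_once(self, base_layers):
        sub = {k: base_layers[k] for k in ("ELE", "BAM", "villages")}
        stack = build_multiscale_stack(sub, scales=(1000,))
        variables = stack.variables()
        assert variables["ELE"] == [1000]
        assert variables["BAM"] == [1000]
        assert variables["Densvil"] == [1000]

    def test_naming_round_trips_through_files(self, base_layers, tmp_path):
        sub = {k: base_layers[k] for k in ("ELE", "BAM", "villages")}
        stack = build_multiscale_stack(sub, scales=(1000, 3000))
        stack.to_dir(tmp_path)
        back = type(stack).from_dir(tmp_path)
        assert sorted(back.names) == sorted(stack.names)
        for name in stack.names:
            assert np.allclose(back[name].values, stack[name].values,
                               equal_nan=True, atol=1e-8)

    def test_misaligned_grids_rejected(self, base_layers):
        bad = dict(base_layers)
        bad["NPP"] = RasterGrid(np.zeros((10, 10)), 250.0, (0, 2500))
        with pytest.raises(ValueError):
            build_multiscale_stack(bad, scales=(1000,))
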