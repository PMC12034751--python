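import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopyfractal.architecture import (
    aboveground_biomass,
    analyze_tree,
    crown_asymmetry,
    crown_base_height,
    crown_length,
    crown_surface_area,
    crown_volume,
    dbh_circle_fit,
    dbh_quadratic_sum,
    layer_hulls,
    max_crown_area,
    mean_crown_radius,
    total_height,
)
from canopyfractal.cloud import PointCloud


def _cylinder(radius, z0, z1, n, rng, center=(0.0, 0.0)):
    theta = rng.uniform(0, 2 * math.pi, n)
    z = rng.uniform(z0, z1, n)
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta), z]
    )


def _sphere_surface(radius, center, n, rng):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * radius + np.asarray(center)


class TestTotalHeight:
    def test_two_points(self):
        cloud = PointCloud(np.array([[0, 0, 0.0], [1, 1, 10.0]]))
        assert total_height(cloud) == 10.0

    def test_vertical_offset_invariance(self, rng):
        xyz = rng.uniform(0, 5, (100, 3))
        assert total_height(PointCloud(xyz)) == total_height(PointCloud(xyz + [0, 0, 5]))


class TestDbh:
    def test_perfect_cylinder(self, rng):
        cloud = PointCloud(_cylinder(0.15, 0.0, 3.0, 5000, rng))
        dbh, flags = dbh_circle_fit(cloud)
        assert dbh == pytest.approx(30.0, abs=0.5)
        assert flags == []

    def test_noisy_cylinder(self, rng):
        xyz = _cylinder(0.15, 0.0, 3.0, 5000, rng)
        xyz[:, :2] += rng.normal(0, 0.005, (5000, 2))
        dbh, _ = dbh_circle_fit(PointCloud(xyz))
        assert dbh == pytest.approx(30.0, abs=2.0)

    def test_sparse_slice_uses_flagged_fallback(self):
        # stem rendered so the breast-height slice holds only 3 points
        slice_pts = np.array([[0.15, 0, 1.3], [-0.15, 0, 1.3], [0, 0.15, 1.32]])
        rest = np.column_stack([np.zeros(50), np.zeros(50), np.linspace(0, 1.0, 50)])
        cloud = PointCloud(np.vstack([rest, slice_pts]))
        dbh, flags = dbh_circle_fit(cloud)
        assert "dbh_two_point_fallback" in flags
        assert dbh == pytest.approx(30.0, abs=1.0)

    def test_two_separated_stems_combined_quadratically(self, rng):
        a = _cylinder(0.15, 0.0, 3.0, 4000, rng, center=(0.0, 0.0))
        b = _cylinder(0.20, 0.0, 3.0, 4000, rng, center=(1.5, 0.0))
        dbh, flags = dbh_circle_fit(PointCloud(np.vstack([a, b])))
        assert any(f.startswith("multi_stem") for f in flags)
        assert dbh == pytest.approx(math.hypot(30.0, 40.0), abs=1.0)


class TestDbhQuadraticSum:
    def test_single_stem_identity(self):
        assert dbh_quadratic_sum([30.0]) == 30.0

    def test_three_four_five(self):
        assert dbh_quadratic_sum([30.0, 40.0]) == pytest.approx(50.0, abs=1e-12)

    @settings(deadline=None)
    @given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=8))
    def test_at_least_max_and_grows(self, dbhs):
        combined = dbh_quadratic_sum(dbhs)
        assert combined >= max(dbhs) - 1e-12
        assert dbh_quadratic_sum(dbhs + [10.0]) > combined

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dbh_quadratic_sum([30.0, 0.0])


class TestCrownBaseHeight:
    def _stem_plus_crown(self, cbh, rng):
        stem = _cylinder(0.10, 0.0, cbh, 3000, rng)
        crown = _sphere_surface(2.0, (0, 0, cbh + 2.0), 20000, rng)
        crown = crown[crown[:, 2] >= cbh]
        return PointCloud(np.vstack([stem, crown]))

    def test_recovers_crown_start(self, rng):
        cloud = self._stem_plus_crown(4.0, rng)
        cbh, flags = crown_base_height(cloud, stem_radius_m=0.10)
        assert cbh == pytest.approx(4.0, abs=0.1)
        assert flags == []

    def test_crown_to_ground_flagged_zero(self, rng):
        crown = _sphere_surface(2.0, (0, 0, 2.0), 20000, rng)
        crown = crown[crown[:, 2] >= 0]
        cbh, flags = crown_base_height(PointCloud(crown), stem_radius_m=0.10)
        assert cbh == 0.0
        assert "cbh_crown_to_ground" in flags

    def test_threshold_factor_insensitive_on_clean_tree(self, rng):
        cloud = self._stem_plus_crown(4.0, rng)
        values = [
            crown_base_height(cloud, 0.10, area_factor=k)[0] for k in (2.0, 3.0, 4.0)
        ]
        assert max(values) - min(values) <= 0.1 + 1e-9  # within one layer


class TestLayerHulls:
    def test_square_layer_area(self):
        pts = np.array([[0, 0, 0.05], [2, 0, 0.05], [2, 2, 0.05], [0, 2, 0.05]])
        layers = layer_hulls(PointCloud(pts), cbh=0.0)
        assert layers[0][1] == pytest.approx(4.0, abs=1e-9)

    def test_sphere_max_layer_near_equator(self, rng):
        crown = _sphere_surface(2.0, (0, 0, 5.0), 40000, rng)
        layers = layer_hulls(PointCloud(crown), cbh=0.0)
        area, height = max_crown_area(layers)
        assert area == pytest.approx(math.pi * 4.0, rel=0.03)
        # heights count from the cloud's lowest point: equator sits one
        # radius above the sphere's bottom
        assert height == pytest.approx(2.0, abs=0.2)

    def test_areas_match_shoelace_oracle(self, rng):
        # independent oracle: sort hull-candidate points by angle, shoelace
        pts = rng.uniform(0, 1, (40, 2))
        z = np.full(40, 0.05)
        layers = layer_hulls(PointCloud(np.column_stack([pts, z])), cbh=0.0)

        def shoelace_of_convex_subset(p):
            # gift-wrap by angle around centroid works for the hull points
            from scipy.spatial import ConvexHull

            h = ConvexHull(p)
            v = p[h.vertices]
            x, y = v[:, 0], v[:, 1]
            return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

        assert layers[0][1] == pytest.approx(shoelace_of_convex_subset(pts), rel=1e-9)

    def test_thin_layers_get_zero_area(self):
        pts = np.array([[0, 0, 0.05], [1, 0, 0.05]])  # collinear pair
        layers = layer_hulls(PointCloud(pts), cbh=0.0)
        assert layers[0][1] == 0.0


class TestMaxCrownArea:
    def test_cone_peaks_at_lowest_layer(self, rng):
        n = 30000
        f = np.sqrt(rng.uniform(0, 1, n))
        theta = rng.uniform(0, 2 * math.pi, n)
        z = 10.0 - 6.0 * f
        r = 2.0 * f
        cone = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        layers = layer_hulls(PointCloud(cone), cbh=4.0)
        _, h = max_crown_area(layers)
        assert h == pytest.approx(4.05, abs=0.1)

    def test_tie_broken_to_lowest(self):
        layers = [(1.05, 3.0), (1.15, 5.0), (1.25, 5.0)]
        area, h = max_crown_area(layers)
        assert (area, h) == (5.0, 1.15)


class TestCrownSurfaceArea:
    def test_dense_sphere_sample(self, rng):
        crown = _sphere_surface(2.0, (0, 0, 5.0), 50000, rng)
        csa = crown_surface_area(PointCloud(crown), cbh=0.0)
        assert csa == pytest.approx(4 * math.pi * 4.0, rel=0.02)

    def test_tetrahedron_closed_form(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        # three right triangles of area 1/2 plus the sqrt(3)/2 face
        expected = 3 * 0.5 + math.sqrt(3) / 2
        assert crown_surface_area(PointCloud(pts), cbh=0.0) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_coplanar_rejected(self):
        pts = np.column_stack([np.arange(10), np.arange(10) * 2.0, np.zeros(10)])
        with pytest.raises(ValueError):
            crown_surface_area(PointCloud(pts), cbh=0.0)

    def test_at_least_twice_max_layer_area(self, conifer_tree, broadleaf_tree):
        # a convex body's surface exceeds twice any planar cross-section
        for _, cloud in (conifer_tree, broadleaf_tree):
            layers = layer_hulls(cloud, cbh=6.0)
            area, _ = max_crown_area(layers)
            csa = crown_surface_area(cloud, cbh=6.0)
            assert csa >= 2 * area


class TestMeanCrownRadius:
    def test_cylindrical_crown(self, rng):
        crown = _cylinder(3.0, 5.0, 10.0, 40000, rng)
        mcr, n_empty = mean_crown_radius(PointCloud(crown), cbh=0.0, axis_xy=(0, 0))
        assert mcr == pytest.approx(3.0, abs=0.05)
        assert n_empty == 0

    def test_single_point_single_sector(self):
        pts = np.array([[2.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
        mcr, n_empty = mean_crown_radius(PointCloud(pts), cbh=0.5, axis_xy=(0, 0))
        assert mcr == 2.0
        assert n_empty == 359

    def test_rotation_invariance(self, rng):
        crown = _cylinder(2.5, 4.0, 9.0, 20000, rng)
        crown[:, 0] += 0.8  # asymmetric about the axis
        rot = crown.copy()
        rot[:, 0], rot[:, 1] = -crown[:, 1], crown[:, 0]  # 90 degrees
        a, _ = mean_crown_radius(PointCloud(crown), 4.0, (0, 0))
        b, _ = mean_crown_radius(PointCloud(rot), 4.0, (0, 0))
        assert a == pytest.approx(b, rel=1e-3)


class TestCrownVolume:
    def test_cylinder_volume(self, rng):
        crown = _cylinder(1.0, 0.0, 5.0, 60000, rng)
        # interior must be filled for layered hulls to see the full disc
        interior = crown * [np.nan, np.nan, np.nan]  # placeholder, replaced below
        r = np.sqrt(rng.uniform(0, 1, 60000))
        theta = rng.uniform(0, 2 * math.pi, 60000)
        interior = np.column_stack(
            [r * np.cos(theta), r * np.sin(theta), rng.uniform(0, 5.0, 60000)]
        )
        layers = layer_hulls(PointCloud(np.vstack([crown, interior])), cbh=0.0)
        assert crown_volume(layers) == pytest.approx(math.pi * 5.0, rel=0.03)

    def test_sphere_volume(self, rng):
        crown = _sphere_surface(2.0, (0, 0, 5.0), 60000, rng)
        layers = layer_hulls(PointCloud(crown), cbh=0.0)
        assert crown_volume(layers) == pytest.approx(4 / 3 * math.pi * 8.0, rel=0.05)

    def test_zero_area_layers_contribute_nothing(self):
        layers = [(0.05, 2.0), (0.15, 0.0), (0.25, 1.0)]
        assert crown_volume(layers) == pytest.approx(0.3, abs=1e-12)


class TestCrownLengthAndAsymmetry:
    @pytest.mark.parametrize("tth, cbh, expected", [(10.0, 4.0, 6.0), (10.0, 0.0, 10.0)])
    def test_crown_length(self, tth, cbh, expected):
        assert crown_length(tth, cbh) == expected

    def test_centered_crown_has_no_asymmetry(self, rng):
        crown = _cylinder(2.0, 4.0, 9.0, 30000, rng)
        assert crown_asymmetry(PointCloud(crown), 4.0, (0.0, 0.0)) == pytest.approx(0.0, abs=0.05)

    def test_offset_crown_distance_recovered(self, rng):
        crown = _sphere_surface(2.0, (1.5, 0.0, 7.0), 30000, rng)
        stem = _cylinder(0.1, 0.0, 5.0, 2000, rng)
        cloud = PointCloud(np.vstack([stem, crown[crown[:, 2] > 5.0]]))
        assert crown_asymmetry(cloud, 5.0, (0.0, 0.0)) == pytest.approx(1.5, abs=0.1)

    def test_rotation_about_stem_axis_invariant(self, rng):
        crown = _sphere_surface(2.0, (1.5, 0.0, 7.0), 30000, rng)
        ang = math.radians(137.0)
        rot = crown.copy()
        rot[:, 0] = crown[:, 0] * math.cos(ang) - crown[:, 1] * math.sin(ang)
        rot[:, 1] = crown[:, 0] * math.sin(ang) + crown[:, 1] * math.cos(ang)
        a = crown_asymmetry(PointCloud(crown), 0.0, (0.0, 0.0))
        b = crown_asymmetry(PointCloud(rot), 0.0, (0.0, 0.0))
        assert a == pytest.approx(b, rel=0.02)


class TestAbovegroundBiomass:
    @pytest.mark.parametrize("v, rho, expected", [(1.0, 500.0, 500.0), (0.2, 450.0, 90.0)])
    def test_product(self, v, rho, expected):
        assert aboveground_biomass(v, rho) == expected

    def test_linear_in_both_arguments(self, rng):
        v, rho = 0.7, 410.0
        assert aboveground_biomass(3 * v, rho) == pytest.approx(3 * aboveground_biomass(v, rho))
        assert aboveground_biomass(v, 2 * rho) == pytest.approx(2 * aboveground_biomass(v, rho))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            aboveground_biomass(0.0, 500.0)


class TestAnalyzeTree:
    def test_recovers_generator_truth(self, broadleaf_tree):
        spec, cloud = broadleaf_tree
        rec = analyze_tree(1, spec.species_label, cloud, stem_base_xy=(0, 0))
        m = rec.metrics
        assert m.tth_m == pytest.approx(spec.tth, abs=0.04)
        assert m.dbh_cm == pytest.approx(spec.stem_dbh_cm[0], abs=1.0)
        assert m.cbh_m == pytest.approx(spec.cbh, abs=0.2)
        assert m.mcr_m == pytest.approx(spec.crown_radius, abs=0.15)
        assert m.max_crownarea_m2 == pytest.approx(math.pi * spec.crown_radius**2, rel=0.05)
        assert m.h_maxarea_m == pytest.approx((spec.cbh + spec.tth) / 2, abs=0.3)
        assert m.crown_asymmetry_m == pytest.approx(0.0, abs=0.1)

    def test_crown_length_identity_machine_precision(self, conifer_tree):
        spec, cloud = conifer_tree
        rec = analyze_tree(1, spec.species_label, cloud, stem_base_xy=(0, 0))
        assert rec.metrics.cl_m == rec.metrics.tth_m - rec.metrics.cbh_m

    def test_horizontal_translation_invariance(self, conifer_tree):
        spec, cloud = conifer_tree
        moved = cloud.translated((25.0, -13.0, 0.0))
        a = analyze_tree(1, "x", cloud, stem_base_xy=(0, 0), compute_db=False).metrics
        b = analyze_tree(1, "x", moved, stem_base_xy=(25.0, -13.0), compute_db=False).metrics
        assert a.tth_m == b.tth_m
        assert a.cbh_m == b.cbh_m
        assert a.mcr_m == pytest.approx(b.mcr_m, rel=1e-9)
        assert a.csa_m2 == pytest.approx(b.csa_m2, rel=1e-9)
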