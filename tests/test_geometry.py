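import math

import numpy as np
import pytest

from icescreen import phantom
from icescreen.geometry import (
    AmbiguousInterfacesError,
    InterfaceSurface,
    fit_surface,
    locate_interfaces,
    surface_tilt,
    thickness_stats,
    z_profile,
)
from icescreen.phantom import SurfaceProfile
from icescreen.volume import Volume
from conftest import small_config


class TestZProfile:
    def test_uniform_volume_gives_constant_profile(self):
        vol = Volume(np.full((20, 8, 8), 3.5, np.float32), 8.0)
        np.testing.assert_allclose(z_profile(vol), 3.5)

    def test_all_zero_volume_gives_zero_profile(self):
        vol = Volume(np.zeros((10, 4, 4), np.float32), 8.0)
        np.testing.assert_allclose(z_profile(vol), 0.0)

    def test_slab_transition_located_within_one_slice(self):
        data = np.zeros((80, 16, 16), np.float32)
        data[30:61] = -0.3  # slab covering z = 24-48.8 nm at 0.8 nm voxels
        vol = Volume(data, 8.0)
        prof = z_profile(vol)
        below = np.where(prof < -0.15)[0]
        assert abs(below[0] - 30) <= 1
        assert abs(below[-1] - 60) <= 1

    def test_empty_mask_rejected(self):
        vol = Volume(np.zeros((10, 4, 4), np.float32), 8.0)
        with pytest.raises(ValueError, match="empty mask"):
            z_profile(vol, np.zeros((4, 4), bool))


class TestFitSurface:
    def test_three_points_on_flat_plane(self):
        pts = np.array([[0, 0, 10.0], [5, 0, 10.0], [0, 5, 10.0]])
        s = fit_surface(pts, order=1)
        assert (s.a, s.b, s.c) == pytest.approx((0, 0, 10), abs=1e-12)
        assert s.fit_residual == pytest.approx(0.0, abs=1e-12)

    def test_exact_slope_recovery(self):
        slope = math.tan(math.radians(5.0))
        x = np.linspace(0, 100, 25)
        pts = np.column_stack([x, np.zeros_like(x) + np.arange(25) % 5, slope * x])
        s = fit_surface(pts, order=1)
        assert s.a == pytest.approx(slope, abs=1e-6)

    def test_noisy_plane_coefficients_within_three_standard_errors(self):
        # Monte-Carlo regression oracle: OLS standard errors for sigma = 2 nm
        rng = np.random.default_rng(0)
        n, sigma = 100, 2.0
        x = rng.uniform(0, 100, n)
        y = rng.uniform(0, 100, n)
        a_true, b_true, c_true = 0.05, -0.02, 40.0
        z = a_true * x + b_true * y + c_true + rng.normal(0, sigma, n)
        s = fit_surface(np.column_stack([x, y, z]), order=1)
        A = np.column_stack([x, y, np.ones(n)])
        cov = sigma**2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        assert abs(s.a - a_true) < 3 * se[0]
        assert abs(s.b - b_true) < 3 * se[1]
        assert abs(s.c - c_true) < 3 * se[2]

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 1.0], [1, 1, 2.0], [2, 2, 3.0], [3, 3, 4.0]])
        with pytest.raises(ValueError, match="degenerate"):
            fit_surface(pts, order=1)


class TestSurfaceTilt:
    def test_horizontal_plane_has_zero_tilt(self):
        assert surface_tilt(InterfaceSurface("bottom", c=40.0)) == 0.0

    def test_pure_x_slope(self):
        s = InterfaceSurface("bottom", a=math.tan(math.radians(10.0)), c=40.0)
        assert surface_tilt(s) == pytest.approx(10.0, abs=1e-9)

    def test_combined_slope_matches_normal_vector_arithmetic(self):
        a = math.tan(math.radians(3.0))
        b = math.tan(math.radians(4.0))
        s = InterfaceSurface("bottom", a=a, b=b, c=0.0)
        expect = math.degrees(math.acos(1.0 / math.sqrt(1 + a * a + b * b)))
        assert surface_tilt(s) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(5.0, abs=0.01)


class TestThicknessStats:
    def test_parallel_flat_surfaces_classified_flat(self, grid_xy):
        xs, ys, *_ = grid_xy
        b = InterfaceSurface("bottom", c=40.0)
        t = InterfaceSurface("top", c=70.0)
        g = thickness_stats(b, t, xs, ys, (76.8, 76.8), 90.0, 10.0)
        assert g.t_center_min == pytest.approx(30.0)
        assert g.t_edge_min == pytest.approx(30.0)
        assert (g.curvature_bottom, g.curvature_top) == ("C2", "C2")

    def test_concave_phantom_classified_c3_with_center_minimum(self, grid_xy):
        xs, ys, *_ = grid_xy
        cfg = small_config(n_particles=0)
        b, t = phantom.ground_truth_surfaces(cfg)
        g = thickness_stats(b, t, xs, ys, (76.8, 76.8), 90.0, 12.0)
        assert (g.curvature_bottom, g.curvature_top) == ("C3", "C3")
        assert g.t_center_min == pytest.approx(30.0, abs=1.0)
        assert g.t_edge_min > g.t_center_min

    def test_thin_center_demoted_to_c4_when_below_minor_axis(self, grid_xy):
        xs, ys, *_ = grid_xy
        cfg = small_config(
            bottom_profile=SurfaceProfile("C4", 4, 40),
            top_profile=SurfaceProfile("C4", 4, 40),
            particle_diameter=15.0,
            n_particles=0,
        )
        b, t = phantom.ground_truth_surfaces(cfg)
        g = thickness_stats(b, t, xs, ys, (76.8, 76.8), 90.0, 15.0)
        assert g.curvature_bottom == "C4"
        assert g.t_center_min < 15.0

    def test_crossing_surfaces_reported_degenerate_not_raised(self, grid_xy):
        xs, ys, *_ = grid_xy
        b = InterfaceSurface("bottom", c=60.0, a=0.1)
        t = InterfaceSurface("top", c=55.0)
        g = thickness_stats(b, t, xs, ys, (76.8, 76.8), 90.0, 10.0)
        assert g.degenerate
        assert np.nanmin(g.thickness_map) == 0.0

    def test_inflating_surfaces_shifts_every_thickness_exactly(self, grid_xy):
        xs, ys, *_ = grid_xy
        cfg = small_config(n_particles=0)
        b, t = phantom.ground_truth_surfaces(cfg)
        g0 = thickness_stats(b, t, xs, ys, (76.8, 76.8), 90.0, 12.0)
        delta = 7.0
        g1 = thickness_stats(
            b.shifted(-delta / 2), t.shifted(delta / 2), xs, ys, (76.8, 76.8), 90.0, 12.0
        )
        np.testing.assert_allclose(
            g1.thickness_map[np.isfinite(g1.thickness_map)],
            g0.thickness_map[np.isfinite(g0.thickness_map)] + delta,
            atol=1e-9,
        )


class TestLocateInterfaces:
    def test_noiseless_gradient_matches_analytic_surfaces_within_one_voxel(
        self, noiseless_phantom, grid_xy, hole_mask
    ):
        cfg, vol, _ = noiseless_phantom
        _, _, X, Y, _, _ = grid_xy
        b, t = locate_interfaces(vol, "gradient", mask=hole_mask)
        tb, tt = phantom.ground_truth_surfaces(cfg)
        for fit, tru in ((b, tb), (t, tt)):
            err = np.abs(fit.evaluate(X, Y) - tru.evaluate(X, Y))[hole_mask]
            assert err.max() <= vol.voxel_nm

    def test_gradient_offsets_recovered_within_two_nm(self, noiseless_phantom):
        cfg, vol, _ = noiseless_phantom
        b, t = locate_interfaces(vol, "gradient")
        tb, tt = phantom.ground_truth_surfaces(cfg)
        cx = cy = 76.8
        assert abs(b.evaluate(cx, cy) - tb.evaluate(cx, cy)) < 2.0
        assert abs(t.evaluate(cx, cy) - tt.evaluate(cx, cy)) < 2.0

    def test_contamination_strategy_within_five_nm(self, grid_xy, hole_mask):
        _, _, X, Y, _, _ = grid_xy
        cfg = small_config(
            n_particles=0, contamination_density=400.0, noise_sigma=0.1, seed=2
        )
        vol, _ = phantom.make_phantom(cfg)
        b, t = locate_interfaces(vol, "contamination")
        tb, tt = phantom.ground_truth_surfaces(cfg)
        for fit, tru in ((b, tb), (t, tt)):
            err = np.abs(fit.evaluate(X, Y) - tru.evaluate(X, Y))[hole_mask]
            assert err.mean() < 5.0
        assert b.locator == "contamination"

    def test_particle_layer_strategy_within_five_nm(self, grid_xy, hole_mask):
        _, _, X, Y, _, _ = grid_xy
        cfg = small_config(
            n_particles=120,
            adsorbed_fraction=1.0,
            layer_split=0.5,
            layer_offset=5.0,
            noise_sigma=0.15,
            seed=14,
        )
        vol, _ = phantom.make_phantom(cfg)
        b, t = locate_interfaces(
            vol, "particle_layer",
            hints={"layer_offset": 5.0, "particle_diameter": 12.0},
        )
        tb, tt = phantom.ground_truth_surfaces(cfg)
        for fit, tru in ((b, tb), (t, tt)):
            err = np.abs(fit.evaluate(X, Y) - tru.evaluate(X, Y))[hole_mask]
            assert err.mean() < 5.0
        assert b.locator == "particle_layer"

    def test_featureless_volume_raises_with_candidates(self):
        vol = Volume(np.zeros((64, 48, 48), np.float32), 8.0)
        with pytest.raises(AmbiguousInterfacesError):
            locate_interfaces(vol, "gradient")

    def test_rotating_ninety_degrees_about_z_preserves_thickness(self, grid_xy):
        xs, ys, *_ = grid_xy
        cfg = small_config(n_particles=0, noise_sigma=0.1, seed=5)
        vol, _ = phantom.make_phantom(cfg)
        rot = Volume(np.rot90(vol.data, k=1, axes=(1, 2)).copy(), vol.voxel_size)
        stats = []
        for v in (vol, rot):
            b, t = locate_interfaces(v, "gradient")
            g = thickness_stats(b, t, xs, ys, (76.8, 76.8), 90.0, 12.0)
            stats.append(g)
        assert stats[0].t_center_min == pytest.approx(
            stats[1].t_center_min, abs=vol.voxel_nm
        )
        assert stats[0].tilt_bottom == pytest.approx(stats[1].tilt_bottom, abs=0.3)
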