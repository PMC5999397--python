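import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import cKDTree

from icescreen import phantom
from icescreen.geometry import InterfaceSurface
from icescreen.particles import (
    adsorbed_fraction,
    assign_to_layers,
    classify_behavior,
    detect_particles,
    layer_count_token,
    layer_saturation,
    layer_tilt,
    projection_overlap,
    LayerModel,
    Particle,
)
from icescreen.volume import Volume
from conftest import small_config


def _flat_pair(zb=40.0, zt=70.0):
    return (InterfaceSurface("bottom", c=zb), InterfaceSurface("top", c=zt))


class TestDetectParticles:
    def test_recall_and_precision_on_snr3_phantom(self, noisy_phantom):
        cfg, vol, gt = noisy_phantom
        dets = detect_particles(vol, (0.7 * 12, 1.4 * 12))
        truth = np.array([p.center for p in gt.particles])
        tree = cKDTree(truth)
        d, i = tree.query(dets[:, :3])
        matched = d < 0.5 * cfg.particle_diameter
        recall = len(set(i[matched])) / len(truth)
        precision = matched.mean()
        assert recall >= 0.9
        assert precision >= 0.9

    def test_noise_only_volume_yields_almost_no_detections(self):
        rng = np.random.default_rng(0)
        vol = Volume(rng.normal(0, 0.233, (160, 192, 192)).astype(np.float32), 8.0)
        dets = detect_particles(vol, (0.7 * 12, 1.4 * 12))
        # volume is 128 x 153.6 x 153.6 nm ~ 0.024 x (500 nm)^3
        assert len(dets) <= 2

    def test_single_sphere_detected_at_its_centre(self):
        data = np.zeros((64, 64, 64), np.float32)
        phantom._render_spheres(data, np.array([[25.6, 25.6, 25.6]]), np.array([6.0]),
                                0.8, -0.7)
        dets = detect_particles(Volume(data, 8.0), (8.0, 16.0))
        assert len(dets) == 1
        assert np.abs(dets[0, :3] - 25.6).max() <= 0.8

    def test_scale_below_nyquist_rejected(self):
        vol = Volume(np.zeros((16, 16, 16), np.float32), 8.0)
        with pytest.raises(ValueError, match="Nyquist"):
            detect_particles(vol, (2.0, 4.0))


class TestAssignToLayers:
    def test_mid_ice_centroids_form_no_layers(self):
        surfaces = _flat_pair(0.0, 100.0)
        pts = np.array([[10.0, 10.0, 50.0], [20.0, 20.0, 55.0], [30.0, 10.0, 45.0]])
        parts, layers = assign_to_layers(pts, surfaces, cutoff=10.0)
        assert layers == []
        assert all(not p.adsorbed and p.side == "none" for p in parts)

    def test_partition_into_exactly_one_group(self, noisy_phantom):
        cfg, vol, gt = noisy_phantom
        pts = np.array([p.center for p in gt.particles])
        surfaces = phantom.ground_truth_surfaces(cfg)
        parts, _ = assign_to_layers(pts, surfaces, cutoff=10.0)
        for p in parts:
            groups = [p.layer_id == 0, p.layer_id == 1, p.layer_id is None]
            assert sum(groups) == 1
            assert p.adsorbed == (min(p.d_bottom, p.d_top) <= 10.0)

    def test_signed_distances_measured_along_z(self):
        surfaces = _flat_pair(40.0, 70.0)
        parts, _ = assign_to_layers(np.array([[5.0, 5.0, 45.0]]), surfaces)
        p = parts[0]
        assert p.d_bottom == pytest.approx(5.0)
        assert p.d_top == pytest.approx(25.0)
        assert p.side == "bottom" and p.layer_id == 0

    def test_crossing_surfaces_rejected(self):
        surfaces = (InterfaceSurface("bottom", c=80.0), InterfaceSurface("top", c=40.0))
        with pytest.raises(ValueError, match="cross"):
            assign_to_layers(np.array([[0.0, 0.0, 60.0]]), surfaces)

    def test_adsorbed_fraction_nondecreasing_in_cutoff(self, noisy_phantom):
        cfg, vol, gt = noisy_phantom
        pts = np.array([p.center for p in gt.particles])
        surfaces = phantom.ground_truth_surfaces(cfg)
        prev = 0.0
        for cutoff in (2.0, 5.0, 8.0, 12.0, 20.0):
            parts, _ = assign_to_layers(pts, surfaces, cutoff=cutoff)
            frac = float(adsorbed_fraction(parts))
            assert frac >= prev
            prev = frac


class TestAdsorbedFraction:
    def test_exact_rational_value(self):
        parts = [
            Particle((0, 0, 0), 10, 1, 1, adsorbed=(k < 9), side="bottom",
                     layer_id=0 if k < 9 else None)
            for k in range(10)
        ]
        assert adsorbed_fraction(parts) == Fraction(9, 10)

    def test_all_adsorbed_gives_one(self):
        parts = [Particle((0, 0, 0), 10, 1, 1, True, "bottom", 0)]
        assert adsorbed_fraction(parts) == 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            adsorbed_fraction([])


class TestLayerTilt:
    def test_coplanar_horizontal_layer(self):
        pts = np.array([[0, 0, 30.0], [50, 0, 30.0], [0, 50, 30.0], [50, 50, 30.0]])
        assert layer_tilt(pts) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("tilt", [6.0, 16.0])
    def test_phantom_layer_tilt_recovered_within_one_degree(self, tilt):
        cfg = small_config(
            n_particles=60, adsorbed_fraction=1.0, layer_split=1.0,
            interface_tilt=tilt, noise_sigma=0.0, seed=int(tilt),
        )
        _, gt = phantom.make_phantom(cfg)
        pts = np.array([p.center for p in gt.particles])
        assert layer_tilt(pts) == pytest.approx(tilt, abs=1.0)


class TestLayerSaturation:
    def test_zero_particles(self):
        assert layer_saturation(0, 10.0, 1e4) == 0.0

    def test_hexagonal_packing_reads_one_hundred_percent(self):
        # construct an explicit hexagonal packing of discs with d = 10 nm
        d = 10.0
        xs, ys = [], []
        y, row = 0.0, 0
        while y < 200:
            x0 = 0.0 if row % 2 == 0 else d / 2
            x = x0
            while x < 200:
                xs.append(x)
                ys.append(y)
                x += d
            y += d * math.sqrt(3) / 2
            row += 1
        area = 200.0 * 200.0
        sat = layer_saturation(len(xs), d, area)
        assert sat == pytest.approx(100.0, abs=2.0)
        half = layer_saturation(len(xs) // 2, d, area)
        assert half == pytest.approx(50.0, abs=2.0)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            layer_saturation(5, 10.0, 0.0)


class TestProjectionOverlap:
    def test_coaxial_pair_fully_overlaps(self):
        pts = np.array([[10.0, 10.0, 20.0], [10.0, 10.0, 80.0]])
        frac, uniq = projection_overlap(pts, 10.0)
        assert frac == 1.0 and uniq == 0

    def test_distant_pair_unique(self):
        pts = np.array([[10.0, 10.0, 20.0], [40.0, 10.0, 80.0]])
        frac, uniq = projection_overlap(pts, 10.0)
        assert frac == 0.0 and uniq == 2

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 120))
    def test_agrees_with_all_pairs_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 150, (n, 3))
        d = float(rng.uniform(3, 25))
        frac, uniq = projection_overlap(pts, d)
        over = np.zeros(n, bool)
        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(pts[i, :2] - pts[j, :2])) <= d:
                    over[i] = over[j] = True
        assert uniq == int((~over).sum())
        assert frac == pytest.approx(over.mean())


class TestClassifyBehavior:
    def _stats(self, model, seed=0, axial=False):
        from icescreen.orientation import orientation_dispersion

        return orientation_dispersion(
            phantom.sample_orientations(model, 200, seed), axial=axial
        )

    def test_non_adsorbed_is_b1(self):
        assert classify_behavior(None) == "B1"

    def test_uniform_orientations_give_b2(self):
        lay = LayerModel(0, "bottom", 5.0, 3.0, 50, 40.0)
        assert classify_behavior(lay, self._stats("uniform")) == "B2"

    def test_two_modes_give_b3(self):
        lay = LayerModel(0, "bottom", 5.0, 3.0, 50, 40.0)
        stats = self._stats([((0, 0, 1), 100.0), ((0, 0, -1), 100.0)])
        assert classify_behavior(lay, stats) == "B3"

    def test_fragment_annotation_gives_b4(self):
        lay = LayerModel(0, "bottom", 5.0, 3.0, 50, 40.0)
        assert classify_behavior(lay, self._stats("uniform"), True) == "B4"

    def test_small_layer_is_unknown(self):
        lay = LayerModel(0, "bottom", 5.0, 3.0, 3, 5.0)
        assert classify_behavior(lay, self._stats("uniform")) == "unknown"


class TestLayerToken:
    def test_two_layers_plus_free_particles(self):
        layers = [
            LayerModel(0, "bottom", 5, 3, 40, 40.0),
            LayerModel(1, "top", 5, 3, 38, 38.0),
        ]
        assert layer_count_token(layers, n_free=10) == "2+"

    def test_single_layer_no_free(self):
        layers = [LayerModel(0, "bottom", 5, 3, 40, 40.0)]
        assert layer_count_token(layers, n_free=1) == "1"

    def test_disagreeing_subregions_emit_range(self):
        layers = [LayerModel(0, "bottom", 5, 3, 40, 40.0)]
        assert layer_count_token(layers, 0, sub_region_tokens=["2"]) == "1-2"
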