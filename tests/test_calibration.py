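"""Depth averaging, registration, tilt correction and height maps."""

import numpy as np
import pytest

from depthplate.calibration import (
    HeightMap,
    average_depth_frames,
    build_height_map,
    compute_height_map,
    median_filter_heights,
    register_calibration,
    registration_translation,
    tilt_correct,
)
from depthplate.errors import EmptyBurst, ShapeMismatch
from depthplate.geometry import PlateGeometry, detect_plate, plate_interior_mask
from depthplate.synthetic import SceneSpec, generate_scene

GEOM = PlateGeometry(center_x=320, center_y=240, radius_hat=129.5)


class TestAverageDepthFrames:
    def test_mean_of_constants(self):
        frames = [np.full((10, 10), 500.0)] * 10
        assert np.array_equal(average_depth_frames(frames), np.full((10, 10), 500.0))

    def test_arithmetic_mean(self):
        frames = [np.full((4, 4), v) for v in (1.0, 2.0, 3.0)]
        assert np.array_equal(average_depth_frames(frames), np.full((4, 4), 2.0))

    def test_variance_reduction(self, rng):
        """Var of a 10-frame mean of sigma=1 noise is ~0.1 mm^2."""
        frames = [rng.normal(500.0, 1.0, (120, 120)) for _ in range(10)]
        var = average_depth_frames(frames).var()
        assert var == pytest.approx(0.1, rel=0.2)

    def test_empty_and_mismatched(self):
        with pytest.raises(EmptyBurst):
            average_depth_frames([])
        with pytest.raises(ShapeMismatch):
            average_depth_frames([np.zeros((4, 4)), np.zeros((4, 5))])


class TestRegistration:
    def test_identity_for_identical_centers(self):
        t = registration_translation(GEOM, GEOM)
        assert (t.t_x, t.t_y) == (0, 0)
        d = np.arange(16.0).reshape(4, 4)
        g = PlateGeometry(center_x=2, center_y=2, radius_hat=2)
        assert np.array_equal(register_calibration(d, g, g), d)

    def test_shift_matches_center_offset(self):
        calib_g = PlateGeometry(center_x=100, center_y=100, radius_hat=50)
        plate_g = PlateGeometry(center_x=105, center_y=97, radius_hat=50)
        d = np.arange(200.0 * 200).reshape(200, 200)
        out = register_calibration(d, calib_g, plate_g)
        # every valid output pixel equals the input shifted by T = (5, -3)
        assert np.array_equal(out[:197, 5:], d[3:, :195])
        assert np.isnan(out[:, :5]).all() and np.isnan(out[197:, :]).all()

    def test_shifted_scene_registers_to_zero_height(self):
        """A 7-px plate shift cancels after registration."""
        scene = generate_scene(SceneSpec(items=(), plate_offset_px=(7, 0), frames=1))
        calib_g = detect_plate(scene.calibration[0].rgb)
        plate_g = detect_plate(scene.plate[0].rgb)
        reg = register_calibration(scene.calibration[0].depth, calib_g, plate_g)
        h = compute_height_map(reg, scene.plate[0].depth)
        interior = plate_interior_mask(plate_g, h.shape) & h.valid
        assert np.abs(h.values[interior]).max() < 0.5


class TestHeightMap:
    def test_subtraction(self):
        h = compute_height_map(np.full((4, 4), 500.0), np.full((4, 4), 490.0))
        assert np.array_equal(h.values, np.full((4, 4), 10.0))

    def test_identical_maps_give_zero(self):
        d = np.full((4, 4), 500.0)
        assert not compute_height_map(d, d).values.any()

    def test_negative_heights_retained(self):
        h = compute_height_map(np.full((4, 4), 500.0), np.full((4, 4), 502.0))
        assert np.array_equal(h.values, np.full((4, 4), -2.0))

    def test_linearity_of_average_and_subtraction(self, rng):
        """Averaging before subtracting equals subtracting averages."""
        calib = [rng.normal(500, 1, (20, 20)) for _ in range(5)]
        plate = [rng.normal(495, 1, (20, 20)) for _ in range(5)]
        a = compute_height_map(average_depth_frames(calib), average_depth_frames(plate))
        b = average_depth_frames(
            [compute_height_map(c, p).values for c, p in zip(calib, plate)]
        )
        np.testing.assert_allclose(a.values, b, atol=1e-9)


class TestTiltCorrect:
    def test_zero_map_unchanged(self):
        h = HeightMap(values=np.zeros((480, 640)))
        out = tilt_correct(h, GEOM)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_planar_ramp_removed(self):
        x = np.arange(640, dtype=float)
        h = HeightMap(values=np.tile(0.01 * x, (480, 1)))
        out = tilt_correct(h, GEOM)
        assert np.abs(out.values).max() < 0.5

    def test_dome_peak_preserved_on_ramp(self, hemisphere_scene):
        truth = hemisphere_scene.truth.height_mm * (20.0 / 30.0)  # 20 mm peak
        x = np.arange(640, dtype=float)
        h = HeightMap(values=truth + 0.01 * x)
        out = tilt_correct(h, GEOM)
        peak_rc = np.unravel_index(np.argmax(truth), truth.shape)
        assert out.values[peak_rc] == pytest.approx(20.0, abs=1.0)

    def test_idempotent(self, rng):
        h = HeightMap(values=rng.normal(0, 2, (480, 640)))
        once = tilt_correct(h, GEOM)
        twice = tilt_correct(once, GEOM)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-6)


class TestMedianFilter:
    def test_constant_unchanged(self):
        h = HeightMap(values=np.full((20, 20), 7.0))
        assert np.array_equal(median_filter_heights(h).values, h.values)

    def test_spike_removed(self):
        v = np.zeros((20, 20))
        v[10, 10] = 100.0
        assert not median_filter_heights(HeightMap(values=v)).values.any()

    def test_window_one_is_identity(self, rng):
        v = rng.normal(0, 1, (20, 20))
        out = median_filter_heights(HeightMap(values=v), window=1)
        assert np.array_equal(out.values, v)


class TestEndToEndEmptyPlate:
    @pytest.mark.parametrize(
        "tilt,offset",
        [
            ((5 / 640, 0.0), (0, 0)),
            ((0.0, 5 / 480), (10, 0)),
            ((3 / 640, 2 / 480), (-7, 6)),
        ],
        ids=["tilt-x", "tilt-y-shift", "tilt-xy-shift"],
    )
    def test_interior_height_near_zero(self, tilt, offset):
        """Tilt <= 5 mm across field + <= 10 px shift: |h| < 0.5 mm at >= 99%."""
        scene = generate_scene(
            SceneSpec(items=(), tilt_mm_per_px=tilt, plate_offset_px=offset, frames=1)
        )
        calib_g = detect_plate(scene.calibration[0].rgb)
        plate_g = detect_plate(scene.plate[0].rgb)
        h = build_height_map(
            [scene.calibration[0].depth], [scene.plate[0].depth], calib_g, plate_g
        )
        interior = plate_interior_mask(plate_g, h.shape) & h.valid
        frac = np.mean(np.abs(h.values[interior]) < 0.5)
        assert frac >= 0.99
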