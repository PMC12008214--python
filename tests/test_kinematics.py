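"""Amplitude pipeline: filtering, displacement, turning points, swings."""

import numpy as np
import pytest

from tremorcam import (
    InvalidBandError,
    MethodVariant,
    NotEstimableError,
    SeriesTooShortError,
    Space,
    bandpass,
    calibrate_scale,
    consecutive_displacement,
    detect_turning_points,
    estimate_amplitude,
    kendall_tau,
    swing_amplitudes,
)
from tremorcam.synthetic import CameraModel, SimConfig, project_to_camera, simulate_hand_trajectory

from conftest import FS, make_trace, sinusoid


class TestBandpass:
    def test_midband_gain_near_unity(self):
        out = bandpass(sinusoid(1.0, 6.0), 2, 10, FS)
        interior = out[len(out) // 4: -len(out) // 4]
        assert np.abs(interior).max() == pytest.approx(1.0, rel=0.05)

    def test_slow_drift_strongly_attenuated(self):
        out = bandpass(100.0 * sinusoid(1.0, 0.3), 2, 10, FS)
        assert np.abs(out).max() < 5.0

    def test_constant_input_maps_to_zero(self):
        out = bandpass(np.full(3600, 42.0), 2, 10, FS)
        assert np.abs(out).max() < 1e-6

    def test_named_errors(self):
        with pytest.raises(InvalidBandError):
            bandpass(np.zeros(500), 10, 2, FS)
        with pytest.raises(InvalidBandError):
            bandpass(np.zeros(500), 2, 70, FS)
        with pytest.raises(SeriesTooShortError):
            bandpass(np.zeros(40), 2, 10, FS)


class TestDisplacement:
    def test_static_trace_has_zero_displacement(self):
        ds = consecutive_displacement(make_trace(np.full(600, 3.0)), MethodVariant.OMC_XYZ)[0]
        np.testing.assert_allclose(ds.raw, 0.0)

    def test_constant_steps(self):
        steps = np.cumsum(np.full(600, 3.0))
        ds = consecutive_displacement(make_trace(steps), MethodVariant.OMC_XYZ)[0]
        np.testing.assert_allclose(ds.raw, 3.0)

    def test_pythagorean_2d_steps(self):
        n = 600
        xy = np.column_stack([3.0 * np.arange(n), 4.0 * np.arange(n)])
        ds = consecutive_displacement(make_trace(xy), MethodVariant.OMC_XYZ)[0]
        np.testing.assert_allclose(ds.raw, 5.0)

    def test_fewer_than_two_detected_frames(self):
        det = np.zeros(600, dtype=bool)
        det[5] = True
        with pytest.raises(NotEstimableError):
            consecutive_displacement(make_trace(sinusoid(5, 4, 5.0), detected=det),
                                     MethodVariant.OMC_XYZ)

    def test_gap_handling_splits_and_pools(self):
        det = np.ones(3600, dtype=bool)
        det[1000:1200] = False  # 1.7 s gap: split
        trace = make_trace(sinusoid(10, 6), detected=det)
        segments = consecutive_displacement(trace, MethodVariant.OMC_XYZ)
        assert len(segments) == 2
        dec = estimate_amplitude(trace, MethodVariant.OMC_XYZ)
        assert dec.n_segments == 2
        assert dec.median_amplitude == pytest.approx(20.0, rel=0.02)


class TestTurningPoints:
    def _series(self, x, fs=FS):
        return consecutive_displacement(make_trace(x, fs=fs), MethodVariant.OMC_XYZ)[0]

    def test_sinusoid_turning_points_at_positional_extremes(self):
        # velocity zeros of a 6 Hz sinusoid over 30 s: 2 f T = 360 reversals
        ds = self._series(sinusoid(10, 6))
        ti = detect_turning_points(ds)
        assert abs(ti.size - 360) <= 1
        extremes = (2 * np.arange(359) + 1) / 24.0 * FS  # analytic extreme times
        nearest = np.round(extremes)
        assert np.max(np.abs(np.sort(ti)[:359] - nearest)) <= 1

    def test_monotone_ramp_yields_empty(self):
        ds = self._series(np.linspace(0, 100, 3600))
        assert detect_turning_points(ds).size == 0

    def test_two_cycles_give_four_interior_reversals(self):
        fs = 480.0
        t = np.arange(0, 2 / 6, 1 / fs)
        ds = self._series(10 * np.sin(2 * np.pi * 6 * t), fs=fs)
        assert abs(detect_turning_points(ds).size - 4) <= 1

    def test_minimum_separation_enforced(self):
        ds = self._series(sinusoid(10, 6))
        ti = detect_turning_points(ds)
        min_sep = int(round(FS / (2 * ds.band[1])))
        assert np.all(np.diff(ti) >= min_sep)


class TestSwings:
    def test_sinusoid_median_swing_is_peak_to_peak(self):
        for f in (4.0, 6.0, 8.0):
            trace = make_trace(sinusoid(10, f))
            dec = estimate_amplitude(trace, MethodVariant.OMC_XYZ)
            assert dec.median_amplitude == pytest.approx(20.0, rel=0.02)

    def test_arc_oscillation_swings_all_equal(self):
        # rotational tremor: oscillation along a circular arc, radius 30 mm
        t = np.arange(0, 30, 1 / FS)
        phi = 0.5 * np.sin(2 * np.pi * 6 * t)
        xy = np.column_stack([30 * np.cos(phi), 30 * np.sin(phi)])
        dec = estimate_amplitude(make_trace(xy), MethodVariant.OMC_XYZ)
        a = dec.swing_amplitudes
        assert a.std() / a.mean() < 0.01
        assert a.mean() == pytest.approx(2 * 0.5 * 30, rel=0.01)  # arc length per half cycle

    def test_constant_speed_circle_is_not_estimable(self):
        t = np.arange(0, 30, 1 / FS)
        xy = np.column_stack([10 * np.cos(2 * np.pi * 6 * t), 10 * np.sin(2 * np.pi * 6 * t)])
        with pytest.raises(NotEstimableError):
            estimate_amplitude(make_trace(xy), MethodVariant.OMC_XYZ)

    def test_ramp_swings_track_envelope(self):
        cfg = SimConfig(amplitude_start_mm=0.0, amplitude_end_mm=20.0, tremor_axis=(1, 0, 0))
        trace, env = simulate_hand_trajectory(cfg)
        dec = estimate_amplitude(trace, MethodVariant.OMC_XYZ)
        truth = np.interp(dec.swing_times, trace.timestamps, env)
        assert kendall_tau(dec.swing_amplitudes, truth).tau > 0.9

    def test_two_turning_points_required(self):
        ds = consecutive_displacement(make_trace(sinusoid(10, 6)), MethodVariant.OMC_XYZ)[0]
        with pytest.raises(NotEstimableError):
            swing_amplitudes(ds, np.array([100]))


class TestCalibration:
    def test_marker_extent_to_mm_per_px(self):
        cal = calibrate_scale((19.0, 19.0))
        assert cal.mm_per_px == (pytest.approx(0.5), pytest.approx(0.5))

    def test_doubling_extent_halves_scale(self):
        a = calibrate_scale((19.0, 19.0))
        b = calibrate_scale((38.0, 38.0))
        assert b.mm_per_px[0] == pytest.approx(a.mm_per_px[0] / 2)

    def test_nonpositive_extent_rejected(self):
        with pytest.raises(Exception):
            calibrate_scale((0.0, 19.0))

    def test_calibrated_pixel_amplitude_matches_pinhole_truth(self, topdown_inplane_scene):
        scene = topdown_inplane_scene
        cal = calibrate_scale(tuple(np.median(scene.marker_extent_px, axis=0)))
        dec = estimate_amplitude(scene.vi_pixel, MethodVariant.VI_XY, cal)
        assert dec.units == "mm"
        assert dec.median_amplitude == pytest.approx(20.0, rel=0.10)


class TestEstimateAmplitude:
    def test_omc_variant_recovers_sinusoid(self, default_scene):
        dec = estimate_amplitude(default_scene.omc, MethodVariant.OMC_XYZ)
        assert dec.median_amplitude == pytest.approx(20.0, rel=0.02)

    def test_normalized_variant_agrees_with_omc_in_good_geometry(self, topdown_inplane_scene):
        scene = topdown_inplane_scene
        cal = calibrate_scale(tuple(np.median(scene.marker_extent_px, axis=0)))
        mp = estimate_amplitude(scene.mp_norm, MethodVariant.MP_NORM_XY, cal).median_amplitude
        omc = estimate_amplitude(scene.omc, MethodVariant.OMC_XYZ).median_amplitude
        assert mp == pytest.approx(omc, rel=0.15)

    def test_world_m_converts_to_mm(self):
        x_m = sinusoid(0.010, 6.0)
        dec = estimate_amplitude(make_trace(x_m, space=Space.WORLD_M), MethodVariant.MP_WORLD_XY)
        assert dec.units == "mm"
        assert dec.median_amplitude == pytest.approx(20.0, rel=0.02)

    def test_undetected_everywhere_not_estimable(self):
        det = np.zeros(3600, dtype=bool)
        with pytest.raises(NotEstimableError):
            estimate_amplitude(make_trace(sinusoid(10, 6), detected=det), MethodVariant.OMC_XYZ)

    def test_scale_equivariance_exact(self):
        xyz = np.column_stack([sinusoid(7, 5), sinusoid(3, 5, phase=0.5), sinusoid(2, 5)])
        m1 = estimate_amplitude(make_trace(xyz), MethodVariant.OMC_XYZ).median_amplitude
        m2 = estimate_amplitude(make_trace(3.7 * xyz), MethodVariant.OMC_XYZ).median_amplitude
        assert m2 == pytest.approx(3.7 * m1, abs=1e-9)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        xyz = np.column_stack([sinusoid(7, 5), sinusoid(3, 5, phase=0.5), sinusoid(2, 5)])
        R = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        m1 = estimate_amplitude(make_trace(xyz), MethodVariant.OMC_XYZ).median_amplitude
        m2 = estimate_amplitude(make_trace(xyz @ R.T), MethodVariant.OMC_XYZ).median_amplitude
        assert m2 == pytest.approx(m1, abs=1e-9)

    def test_projected_amplitude_decreases_as_axis_leaves_image_plane(self):
        cam = CameraModel(elevation_deg=-90)
        values = []
        for ang in np.deg2rad([0, 15, 30, 45, 60, 75]):
            cfg = SimConfig(tremor_axis=(np.cos(ang), 0.0, np.sin(ang)), amplitude_start_mm=10)
            proj = project_to_camera(simulate_hand_trajectory(cfg)[0], cam)
            values.append(estimate_amplitude(proj.trace, MethodVariant.VI_XY).median_amplitude)
        assert np.all(np.diff(values) < 0)
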