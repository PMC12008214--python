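"""Synthetic tremulous-hand generator: geometry, noise and cohort structure."""

import numpy as np
import pytest

from tremorcam import (
    BehindCameraError,
    CameraModel,
    ConfigError,
    NoiseModel,
    SimConfig,
    Space,
    apply_tracking_noise,
    build_scene,
    normalize_to_frame,
    project_to_camera,
    simulate_hand_trajectory,
    synthesize_cohort,
    synthesize_imu,
    tetras_from_amplitude,
    welch_spectrum,
)
from tremorcam.synthetic import HAND_TEMPLATE_MM


class TestHandTrajectory:
    def test_peak_to_peak_is_twice_half_amplitude(self):
        trace, _ = simulate_hand_trajectory(
            SimConfig(tremor_frequency_hz=6, amplitude_start_mm=10, tremor_axis=(1, 0, 0)))
        x = trace.landmark(12)[:, 0]
        assert np.ptp(x) == pytest.approx(20.0, rel=1e-3)

    def test_ramp_envelope_is_linear(self):
        _, env = simulate_hand_trajectory(
            SimConfig(amplitude_start_mm=0.0, amplitude_end_mm=20.0, duration_s=30.0))
        mid = env[len(env) // 2]
        assert mid == pytest.approx(10.0, abs=0.02)
        assert np.all(np.diff(env) >= 0)

    def test_deterministic_given_seed(self):
        cfg = SimConfig(frequency_jitter_sd_hz=0.2, amplitude_noise_cv=0.05, seed=7)
        a, _ = simulate_hand_trajectory(cfg)
        b, _ = simulate_hand_trajectory(cfg)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_rigid_motion_of_all_landmarks(self):
        trace, _ = simulate_hand_trajectory(SimConfig())
        rel = trace.positions - trace.positions[:, :1, :]
        assert np.abs(rel - rel[0][None]).max() < 1e-9

    def test_noiseless_world_trace_has_single_spectral_line(self):
        trace, _ = simulate_hand_trajectory(SimConfig(tremor_frequency_hz=5.0))
        x = trace.landmark(12)[:, 2]
        sp = welch_spectrum(x - x.mean(), trace.sample_rate)
        assert sp.frequencies[np.argmax(sp.psd[:, 0])] == pytest.approx(5.0, abs=sp.bin_width)

    @pytest.mark.parametrize("bad", [
        dict(tremor_frequency_hz=-1), dict(tremor_frequency_hz=80),
        dict(amplitude_start_mm=-2), dict(duration_s=0),
        dict(tremor_axis=(0, 0, 0)), dict(amplitude_end_mm=float("nan")),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            SimConfig(**bad)


class TestProjection:
    def test_scene_center_projects_to_principal_point(self):
        trace, _ = simulate_hand_trajectory(SimConfig(amplitude_start_mm=0.0))
        cam = CameraModel(azimuth_deg=0, elevation_deg=0)
        proj = project_to_camera(trace, cam)
        center_px = np.nanmean(proj.trace.positions.reshape(-1, 2), axis=0)
        # the rest centroid is the orbit center, hence on the optical axis
        np.testing.assert_allclose(center_px, cam.principal_point_px, atol=0.5)

    def test_in_plane_pixel_amplitude_follows_pinhole_arithmetic(self):
        # half-amplitude 10 mm at 1.5 m with f = 1500 px -> 10 px
        trace, _ = simulate_hand_trajectory(
            SimConfig(tremor_axis=(1, 0, 0), amplitude_start_mm=10.0))
        proj = project_to_camera(trace, CameraModel(elevation_deg=-90))
        x = proj.trace.landmark(12)[:, 0]
        assert np.ptp(x) / 2 == pytest.approx(10.0, rel=0.02)

    def test_optical_axis_tremor_is_foreshortened(self):
        trace, _ = simulate_hand_trajectory(
            SimConfig(tremor_axis=(0, 0, 1), amplitude_start_mm=10.0))
        proj = project_to_camera(trace, CameraModel(elevation_deg=-90))
        tip = proj.trace.landmark(12)
        assert np.ptp(tip[:, 0]) < 1.0 and np.ptp(tip[:, 1]) < 1.0

    def test_pixel_amplitude_scales_with_focal_over_distance(self):
        trace, _ = simulate_hand_trajectory(
            SimConfig(tremor_axis=(1, 0, 0), amplitude_start_mm=10.0))
        base = project_to_camera(trace, CameraModel(elevation_deg=-90))
        double_f = project_to_camera(trace, CameraModel(elevation_deg=-90, focal_length_px=3000))
        half_d = project_to_camera(trace, CameraModel(elevation_deg=-90, distance_m=0.75))
        amp = lambda p: np.ptp(p.trace.landmark(12)[:, 0])
        assert amp(double_f) == pytest.approx(2 * amp(base), rel=0.02)
        assert amp(half_d) == pytest.approx(2 * amp(base), rel=0.02)

    def test_point_behind_camera_names_frame(self):
        trace, _ = simulate_hand_trajectory(SimConfig(amplitude_start_mm=0.0))
        with pytest.raises(BehindCameraError) as err:
            project_to_camera(trace, CameraModel(distance_m=0.001))
        assert err.value.frame_index == 0

    def test_normalize_round_trip(self):
        trace, _ = simulate_hand_trajectory(SimConfig(tremor_axis=(1, 0, 0)))
        pixel = project_to_camera(trace, CameraModel(elevation_deg=-90)).trace
        norm = normalize_to_frame(pixel)
        assert norm.space is Space.NORMALIZED
        np.testing.assert_allclose(norm.to_pixel().positions, pixel.positions,
                                   rtol=1e-12, atol=1e-12)


class TestTrackingNoise:
    def _pixel_trace(self):
        trace, _ = simulate_hand_trajectory(SimConfig(tremor_axis=(1, 0, 0)))
        return project_to_camera(trace, CameraModel(elevation_deg=-90)).trace

    def test_exponent_zero_gives_base_confidence_everywhere(self):
        noise = NoiseModel(confidence_view_exponent=0.0, confidence_noise_sd=0.0,
                           dropout_threshold=0.0, seed=1)
        out = apply_tracking_noise(self._pixel_trace(), noise, CameraModel(elevation_deg=0))
        assert out.detected.all()
        np.testing.assert_allclose(out.confidence, noise.confidence_base)

    def test_palm_plane_view_drops_every_frame(self):
        noise = NoiseModel(confidence_noise_sd=0.0, dropout_threshold=0.1, seed=1)
        out = apply_tracking_noise(self._pixel_trace(), noise, CameraModel(elevation_deg=0))
        assert not out.detected.any()
        assert np.all(np.isnan(out.positions))

    def test_jitter_marginal_sd_matches_model(self):
        clean = self._pixel_trace()
        noise = NoiseModel(jitter_sd_px=1.0, confidence_noise_sd=0.0,
                           dropout_threshold=0.0, seed=5)
        out = apply_tracking_noise(clean, noise, CameraModel(elevation_deg=-90))
        resid = (out.positions - clean.positions)[:, :, 0]
        assert resid.std() == pytest.approx(1.0, rel=0.05)

    def test_deterministic_given_seed(self):
        clean = self._pixel_trace()
        noise = NoiseModel(seed=9)
        a = apply_tracking_noise(clean, noise, CameraModel())
        b = apply_tracking_noise(clean, noise, CameraModel())
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.confidence, b.confidence)


class TestImu:
    def test_static_hand_reads_pure_gravity(self):
        trace, _ = simulate_hand_trajectory(SimConfig(amplitude_start_mm=0.0))
        imu = synthesize_imu(trace, noise_sd=0.0)
        np.testing.assert_allclose(np.linalg.norm(imu.accel, axis=1), 9.81, atol=1e-6)

    def test_sinusoid_acceleration_amplitude_closed_form(self):
        # |a| = A (2 pi f)^2 = 0.01 m * (2 pi 6)^2 = 14.2 m/s^2
        trace, _ = simulate_hand_trajectory(
            SimConfig(tremor_axis=(1, 0, 0), amplitude_start_mm=10.0, tremor_frequency_hz=6.0))
        imu = synthesize_imu(trace, noise_sd=0.0)
        interior = imu.accel[200:-200, 0]
        assert np.abs(interior).max() == pytest.approx(0.01 * (2 * np.pi * 6) ** 2, rel=0.01)

    def test_imu_spectrum_peaks_at_tremor_frequency(self, default_scene):
        from tremorcam import imu_peak_frequency

        peak = imu_peak_frequency(default_scene.imu)
        assert peak.present
        assert peak.peak_frequency == pytest.approx(6.0, abs=peak.bin_width)


class TestCohort:
    def test_cohort_structure_and_monotone_scores(self):
        subjects = synthesize_cohort(n_subjects=8, duration_s=5.0, seed=0)
        assert len(subjects) == 8
        amps = np.array([s.true_peak_to_peak_mm for s in subjects])
        scores = np.array([s.tetras_score for s in subjects])
        assert np.all(amps > 0)
        order = np.argsort(amps)
        assert np.all(np.diff(scores[order]) >= 0)

    def test_tetras_map_boundaries(self):
        assert tetras_from_amplitude(0.5) == 0.0
        assert tetras_from_amplitude(1.5) == 0.5
        assert tetras_from_amplitude(400.0) == 5.0
        custom = [(5.0, 1.0), (50.0, 2.0)]
        assert tetras_from_amplitude(10.0, custom) == 1.0

    def test_deterministic_given_seed(self):
        a = synthesize_cohort(n_subjects=2, duration_s=5.0, seed=3)
        b = synthesize_cohort(n_subjects=2, duration_s=5.0, seed=3)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.scene.mp_norm.positions,
                                          s2.scene.mp_norm.positions)
            assert s1.tetras_score == s2.tetras_score

    def test_empty_range_rejected(self):
        with pytest.raises(ConfigError):
            synthesize_cohort(amplitude_range_mm=(0.0, 10.0))
        with pytest.raises(ConfigError):
            synthesize_cohort(n_subjects=0)


class TestScene:
    def test_traces_share_time_origin_and_template_shape(self, default_scene):
        assert HAND_TEMPLATE_MM.shape == (21, 3)
        for tr in (default_scene.world_truth, default_scene.mp_norm,
                   default_scene.mp_world, default_scene.vi_pixel, default_scene.omc):
            assert tr.timestamps[0] == 0.0
        assert default_scene.imu.timestamps[0] == 0.0
        assert default_scene.imu.sample_rate == 200.0
        assert default_scene.omc.sample_rate == 100.0

    def test_scene_deterministic_given_seeds(self):
        a = build_scene(SimConfig(seed=5), noise=NoiseModel(seed=6))
        b = build_scene(SimConfig(seed=5), noise=NoiseModel(seed=6))
        np.testing.assert_array_equal(a.mp_norm.positions, b.mp_norm.positions)
        np.testing.assert_array_equal(a.imu.accel, b.imu.accel)
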