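"""Synthetic tremulous-hand scenes with co-registered ground truth.

This module generates everything the analysis pipeline consumes, at desk
scale and fully seeded: a rigid 21-landmark hand oscillating quasi-
sinusoidally in 3D (the noiseless world truth), a pinhole-camera view of it
producing pixel- and frame-normalized landmark traces with view-dependent
detection confidence, landmark jitter and frame dropouts (emulating the
output statistics of smartphone hand-tracking frameworks), a down-sampled
lightly-noisy metric trace (emulating marker-based optical motion capture),
and a tri-axial accelerometer series including gravity.

The camera orbits the hand on a half-sphere (azimuth/elevation in degrees,
default 15° grid) at fixed distance, which is what makes the accuracy-vs-
amplitude trade-off of viewpoint selection observable: a tremor along the
palm normal is foreshortened to near zero in a top-down view (where tracking
confidence is highest) and fully visible in a frontal view (where tracking
fails most often).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import lfilter

from .errors import BehindCameraError, ConfigError
from .trace import ImuSeries, MIDDLE_FINGERTIP, Space, TrajectoryTrace

__all__ = [
    "SimConfig",
    "CameraModel",
    "NoiseModel",
    "CameraProjection",
    "SyntheticScene",
    "CohortSubject",
    "HAND_TEMPLATE_MM",
    "MARKER_DIAMETER_MM",
    "DEFAULT_TETRAS_THRESHOLDS",
    "simulate_hand_trajectory",
    "project_to_camera",
    "append_depth_channel",
    "normalize_to_frame",
    "apply_tracking_noise",
    "synthesize_imu",
    "synthesize_cohort",
    "tetras_from_amplitude",
    "build_scene",
]

#: Diameter of the reflective fiducial marker at the fingertip (mm), used for
#: pixel-to-millimetre scale calibration.
MARKER_DIAMETER_MM = 9.5

# Splayed right hand at rest, palm in the x/y plane (palm normal +z), wrist at
# the origin, fingers pointing +y, thumb on the +x side.  Millimetres.  The
# topology is the common 21-point convention (0 wrist; 1-4 thumb; 5-8 index;
# 9-12 middle; 13-16 ring; 17-20 pinky).  Fingers do not articulate: the
# analysis only reads the middle fingertip of a rigidly shaking hand.
HAND_TEMPLATE_MM: np.ndarray = np.array(
    [
        [0.0, 0.0, 0.0],      # 0  wrist
        [25.0, 20.0, 0.0],    # 1  thumb CMC
        [45.0, 45.0, 0.0],    # 2  thumb MCP
        [55.0, 65.0, 0.0],    # 3  thumb IP
        [60.0, 80.0, 0.0],    # 4  thumb tip
        [30.0, 95.0, 0.0],    # 5  index MCP
        [33.0, 125.0, 0.0],   # 6  index PIP
        [35.0, 145.0, 0.0],   # 7  index DIP
        [36.0, 160.0, 0.0],   # 8  index tip
        [10.0, 100.0, 0.0],   # 9  middle MCP
        [11.0, 135.0, 0.0],   # 10 middle PIP
        [12.0, 158.0, 0.0],   # 11 middle DIP
        [12.0, 175.0, 0.0],   # 12 middle tip
        [-10.0, 95.0, 0.0],   # 13 ring MCP
        [-12.0, 128.0, 0.0],  # 14 ring PIP
        [-13.0, 148.0, 0.0],  # 15 ring DIP
        [-14.0, 163.0, 0.0],  # 16 ring tip
        [-28.0, 85.0, 0.0],   # 17 pinky MCP
        [-32.0, 108.0, 0.0],  # 18 pinky PIP
        [-34.0, 123.0, 0.0],  # 19 pinky DIP
        [-36.0, 135.0, 0.0],  # 20 pinky tip
    ]
)

# Ordinal severity score from peak-to-peak tremor amplitude (mm).  These
# thresholds are a configurable package approximation of clinical performance-
# item amplitude anchors (0 none … 5 severe), with half-point scores at the
# geometric midpoints of each band; they are NOT the published anchor table.
DEFAULT_TETRAS_THRESHOLDS: tuple[tuple[float, float], ...] = tuple(
    (lo, s)
    for lo, s in [
        (1.0, 0.5),
        (math.sqrt(1.0 * 10.0), 1.0),
        (10.0, 1.5),
        (math.sqrt(10.0 * 30.0), 2.0),
        (30.0, 2.5),
        (math.sqrt(30.0 * 100.0), 3.0),
        (100.0, 3.5),
        (math.sqrt(100.0 * 200.0), 4.0),
        (200.0, 4.5),
        (math.sqrt(200.0 * 400.0), 5.0),
    ]
)

_LANDMARK_IDS = np.arange(21)
_PALM_LANDMARKS = (0, 5, 9, 13, 17)
_GRAVITY_MS2 = 9.81


def _unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,) or not np.all(np.isfinite(v)):
        raise ConfigError(f"{name} must be a finite 3-vector")
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise ConfigError(f"{name} must have non-zero norm")
    return v / n


def _require_finite(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ConfigError(f"{name} must be finite, got {value}")
    return value


@dataclass
class SimConfig:
    """Parameters of one simulated tremor recording.

    ``amplitude_start_mm``/``amplitude_end_mm`` are *half*-amplitudes of the
    sinusoidal displacement (the peak-to-peak excursion is twice this); the
    envelope ramps linearly between them over the recording.  ``tremor_axis``
    and ``palm_normal`` are unit vectors in the hand-local frame; the default
    tremor axis is the palm normal (an up-down hand flap).
    """

    tremor_frequency_hz: float = 6.0
    amplitude_start_mm: float = 10.0
    amplitude_end_mm: float | None = None
    duration_s: float = 30.0
    sample_rate_hz: float = 120.0
    tremor_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    palm_normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    wrist_position_m: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frequency_jitter_sd_hz: float = 0.0
    amplitude_noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.tremor_frequency_hz = _require_finite(self.tremor_frequency_hz, "tremor_frequency_hz")
        self.duration_s = _require_finite(self.duration_s, "duration_s")
        self.sample_rate_hz = _require_finite(self.sample_rate_hz, "sample_rate_hz")
        self.amplitude_start_mm = _require_finite(self.amplitude_start_mm, "amplitude_start_mm")
        if self.amplitude_end_mm is None:
            self.amplitude_end_mm = self.amplitude_start_mm
        self.amplitude_end_mm = _require_finite(self.amplitude_end_mm, "amplitude_end_mm")
        self.frequency_jitter_sd_hz = _require_finite(self.frequency_jitter_sd_hz, "frequency_jitter_sd_hz")
        self.amplitude_noise_cv = _require_finite(self.amplitude_noise_cv, "amplitude_noise_cv")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.sample_rate_hz <= 0:
            raise ConfigError("sample_rate_hz must be positive")
        if not 0 < self.tremor_frequency_hz < self.sample_rate_hz / 2:
            raise ConfigError("tremor_frequency_hz must lie in (0, sample_rate/2)")
        if self.amplitude_start_mm < 0 or self.amplitude_end_mm < 0:
            raise ConfigError("amplitudes must be non-negative")
        if self.frequency_jitter_sd_hz < 0 or self.amplitude_noise_cv < 0:
            raise ConfigError("noise magnitudes must be non-negative")
        self.tremor_axis = tuple(_unit(self.tremor_axis, "tremor_axis"))
        self.palm_normal = tuple(_unit(self.palm_normal, "palm_normal"))
        wp = np.asarray(self.wrist_position_m, dtype=float)
        if wp.shape != (3,) or not np.all(np.isfinite(wp)):
            raise ConfigError("wrist_position_m must be a finite 3-vector")
        self.wrist_position_m = tuple(wp)
        self.seed = int(self.seed)


@dataclass
class CameraModel:
    """Pinhole camera on the viewing half-sphere.

    ``azimuth_deg``/``elevation_deg`` place the camera on a sphere of radius
    ``distance_m`` around the hand's rest centroid; elevation 0° is a frontal
    (horizontal) view, −90° is straight top-down.  Image origin is top-left
    with y increasing downward.
    """

    azimuth_deg: float = 0.0
    elevation_deg: float = -45.0
    distance_m: float = 1.5
    focal_length_px: float = 1500.0
    principal_point_px: tuple[float, float] | None = None
    resolution_px: tuple[int, int] = (1920, 1080)

    def __post_init__(self):
        self.azimuth_deg = _require_finite(self.azimuth_deg, "azimuth_deg")
        self.elevation_deg = _require_finite(self.elevation_deg, "elevation_deg")
        self.distance_m = _require_finite(self.distance_m, "distance_m")
        self.focal_length_px = _require_finite(self.focal_length_px, "focal_length_px")
        if self.distance_m <= 0 or self.focal_length_px <= 0:
            raise ConfigError("distance_m and focal_length_px must be positive")
        w, h = int(self.resolution_px[0]), int(self.resolution_px[1])
        if w <= 0 or h <= 0:
            raise ConfigError("resolution components must be positive")
        self.resolution_px = (w, h)
        if self.principal_point_px is None:
            self.principal_point_px = (w / 2.0, h / 2.0)
        else:
            self.principal_point_px = (float(self.principal_point_px[0]), float(self.principal_point_px[1]))

    def _radial_unit(self) -> np.ndarray:
        az = math.radians(self.azimuth_deg)
        el = math.radians(self.elevation_deg)
        return np.array([math.cos(el) * math.sin(az), math.cos(el) * math.cos(az), -math.sin(el)])

    def position_m(self, scene_center_m: np.ndarray) -> np.ndarray:
        return np.asarray(scene_center_m, dtype=float) + self.distance_m * self._radial_unit()

    def view_direction(self) -> np.ndarray:
        """Unit vector from the camera toward the scene center."""
        return -self._radial_unit()

    def rotation(self) -> np.ndarray:
        """World→camera rotation; rows are (right, down, forward)."""
        fwd = self.view_direction()
        up = np.array([0.0, 0.0, 1.0])
        if abs(float(fwd @ up)) > 0.999:
            up = np.array([0.0, 1.0, 0.0])
        right = np.cross(fwd, up)
        right /= np.linalg.norm(right)
        down = np.cross(fwd, right)
        return np.stack([right, down, fwd])


@dataclass
class NoiseModel:
    """Statistical model of hand-tracking imperfections.

    Per-frame confidence is ``clip(confidence_base * |cos θ|^exponent +
    N(0, confidence_noise_sd), 0, 1)`` where θ is the angle between the palm
    normal and the viewing direction; frames below ``dropout_threshold`` are
    undetected.  Landmark jitter is AR(1)-correlated in time (tracking noise
    on video is strongly frame-to-frame correlated) with the given marginal
    standard deviation; the estimated-depth channel is noisier than the image
    plane by ``depth_jitter_factor`` and carries slow multiplicative scale
    noise (the "2.5D" depth uncertainty).
    """

    jitter_sd_px: float = 0.5
    jitter_sd_mm: float = 2.0
    jitter_ar1: float = 0.8
    depth_jitter_factor: float = 3.0
    depth_scale_noise_cv: float = 0.10
    world_scale_noise_cv: float = 0.10
    confidence_base: float = 0.95
    confidence_view_exponent: float = 2.0
    confidence_noise_sd: float = 0.05
    dropout_threshold: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("jitter_sd_px", "jitter_sd_mm", "depth_jitter_factor",
                     "depth_scale_noise_cv", "world_scale_noise_cv",
                     "confidence_view_exponent", "confidence_noise_sd"):
            v = _require_finite(getattr(self, name), name)
            if v < 0:
                raise ConfigError(f"{name} must be non-negative")
            setattr(self, name, v)
        self.jitter_ar1 = _require_finite(self.jitter_ar1, "jitter_ar1")
        if not 0 <= self.jitter_ar1 < 1:
            raise ConfigError("jitter_ar1 must lie in [0, 1)")
        self.confidence_base = _require_finite(self.confidence_base, "confidence_base")
        self.dropout_threshold = _require_finite(self.dropout_threshold, "dropout_threshold")
        if not 0 <= self.confidence_base <= 1 or not 0 <= self.dropout_threshold <= 1:
            raise ConfigError("confidence_base and dropout_threshold must lie in [0, 1]")
        self.seed = int(self.seed)


def _rotation_from_z(target: np.ndarray) -> np.ndarray:
    """Minimal rotation taking +z onto ``target`` (unit vector)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(z @ target)
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, target)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def simulate_hand_trajectory(config: SimConfig) -> tuple[TrajectoryTrace, np.ndarray]:
    """Noiseless rigid 3D hand trajectory plus its true amplitude envelope.

    The fingertip position is ``rest + envelope(t)·sin(φ(t))·axis`` with a
    linear envelope and a phase accumulating optional cycle-to-cycle
    frequency jitter; all 21 landmarks translate rigidly with it.

    Returns
    -------
    (trace, envelope)
        World-space trace in mm and the per-frame half-amplitude envelope
        (mm), linear from ``amplitude_start_mm`` to ``amplitude_end_mm``.
    """
    fs = config.sample_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(config.seed)

    f0 = config.tremor_frequency_hz
    if config.frequency_jitter_sd_hz > 0:
        n_cycles = int(math.ceil(f0 * config.duration_s * 1.5)) + 3
        freqs = np.maximum(f0 + config.frequency_jitter_sd_hz * rng.standard_normal(n_cycles), 0.1 * f0)
        knot_t = np.concatenate([[0.0], np.cumsum(1.0 / freqs)])
        knot_phase = 2 * np.pi * np.arange(n_cycles + 1)
        phase = np.interp(t, knot_t, knot_phase)
    else:
        phase = 2 * np.pi * f0 * t

    envelope = np.linspace(config.amplitude_start_mm, config.amplitude_end_mm, n)
    motion_env = envelope
    if config.amplitude_noise_cv > 0:
        n_cycles = int(math.ceil(f0 * config.duration_s)) + 2
        knot_t = np.linspace(0, config.duration_s, n_cycles)
        gain = np.maximum(1 + config.amplitude_noise_cv * rng.standard_normal(n_cycles), 0.0)
        motion_env = envelope * np.interp(t, knot_t, gain)

    rot = _rotation_from_z(np.asarray(config.palm_normal))
    base = HAND_TEMPLATE_MM @ rot.T + 1000.0 * np.asarray(config.wrist_position_m)
    axis = rot @ np.asarray(config.tremor_axis)
    disp = (motion_env * np.sin(phase))[:, None] * axis[None, :]
    positions = base[None, :, :] + disp[:, None, :]

    trace = TrajectoryTrace(
        timestamps=t,
        positions=positions,
        space=Space.WORLD_MM,
        landmark_ids=_LANDMARK_IDS,
        confidence=np.ones(n),
        detected=np.ones(n, dtype=bool),
        sample_rate=fs,
    )
    return trace, envelope


@dataclass
class CameraProjection:
    """Pinhole projection of a world trace.

    ``trace`` holds x/y pixel coordinates; ``depth_m`` is the per-landmark
    distance along the optical axis (used for the emulated depth channel) and
    ``marker_extent_px`` the projected x/y size of the fingertip fiducial
    marker, rounded to whole pixels as a pixel measurement would be.
    """

    trace: TrajectoryTrace
    depth_m: np.ndarray
    marker_extent_px: np.ndarray


def project_to_camera(world_trace: TrajectoryTrace, camera: CameraModel) -> CameraProjection:
    """Project a metric world trace through the pinhole camera.

    Raises :class:`BehindCameraError` naming the first offending frame if any
    point lies on or behind the camera plane.
    """
    if world_trace.space not in (Space.WORLD_MM, Space.WORLD_M):
        raise ConfigError("project_to_camera requires a world-space trace")
    scale = 0.001 if world_trace.space is Space.WORLD_MM else 1.0
    pts = world_trace.positions * scale  # (T, L, 3) metres
    center = np.nanmean(pts.reshape(-1, 3), axis=0)
    cam_pos = camera.position_m(center)
    R = camera.rotation()
    cam = (pts - cam_pos) @ R.T
    z = cam[..., 2]
    finite = np.isfinite(z)
    if np.any(finite & (z <= 0)):
        bad = int(np.argmax(np.any(np.isfinite(cam[..., 2]) & (cam[..., 2] <= 0), axis=1)))
        raise BehindCameraError(bad)
    f = camera.focal_length_px
    cx, cy = camera.principal_point_px
    uv = np.empty(cam.shape[:2] + (2,))
    uv[..., 0] = f * cam[..., 0] / z + cx
    uv[..., 1] = f * cam[..., 1] / z + cy

    tip = world_trace.landmark_index(MIDDLE_FINGERTIP)
    marker = np.rint(f * (MARKER_DIAMETER_MM / 1000.0) / z[:, tip, None].repeat(2, axis=1))

    trace = TrajectoryTrace(
        timestamps=world_trace.timestamps,
        positions=uv,
        space=Space.PIXEL,
        landmark_ids=world_trace.landmark_ids,
        confidence=world_trace.confidence,
        detected=world_trace.detected,
        sample_rate=world_trace.sample_rate,
        frame_resolution=camera.resolution_px,
    )
    return CameraProjection(trace=trace, depth_m=z, marker_extent_px=marker)


def append_depth_channel(projection: CameraProjection, camera: CameraModel) -> TrajectoryTrace:
    """Add a pixel-scale pseudo-depth channel to a projected trace.

    The channel is the true depth deviation re-expressed on the same scale as
    the image x axis (``f·Δdepth/depth``), emulating frameworks whose depth
    output is "roughly the same scale as x"; its extra noise is added later
    by :func:`apply_tracking_noise`.
    """
    t2 = projection.trace
    ref = float(np.nanmedian(projection.depth_m))
    z_px = camera.focal_length_px * (projection.depth_m - ref) / ref
    positions = np.concatenate([t2.positions, z_px[..., None]], axis=2)
    return t2.replace(positions=positions)


def normalize_to_frame(pixel_trace: TrajectoryTrace, resolution: tuple[int, int] | None = None) -> TrajectoryTrace:
    """Pixel → frame-normalized coordinates (x and z by width, y by height)."""
    if resolution is not None:
        pixel_trace = pixel_trace.replace(frame_resolution=resolution)
    return pixel_trace.to_normalized()


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], rho: float) -> np.ndarray:
    """Unit-variance AR(1) noise along axis 0, stationary after a burn-in."""
    burn = 50 if rho > 0 else 0
    e = rng.standard_normal((shape[0] + burn,) + shape[1:])
    if rho == 0:
        return e
    x = lfilter([math.sqrt(1 - rho**2)], [1.0, -rho], e, axis=0)
    return x[burn:]


def _smooth_noise(rng: np.random.Generator, t: np.ndarray, cv: float, knot_hz: float = 1.0) -> np.ndarray:
    """Slow multiplicative noise field: N(0, cv) at ~1 Hz knots, interpolated."""
    if cv == 0:
        return np.zeros_like(t)
    n_knots = max(int(math.ceil((t[-1] - t[0]) * knot_hz)) + 2, 2)
    knot_t = np.linspace(t[0], t[-1], n_knots)
    return np.interp(t, knot_t, cv * rng.standard_normal(n_knots))


def apply_tracking_noise(
    trace: TrajectoryTrace,
    noise: NoiseModel,
    camera: CameraModel,
    palm_normal: Sequence[float] = (0.0, 0.0, 1.0),
    seed: int | None = None,
) -> TrajectoryTrace:
    """Degrade a trace with confidence-gated dropouts and landmark jitter.

    Deterministic given ``seed`` (defaults to ``noise.seed``).  Jitter units
    follow the trace space: pixels for pixel/normalized traces, millimetres
    for world traces; a third (depth) axis receives ``depth_jitter_factor``
    times the jitter plus slow multiplicative scale noise.
    """
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    n_palm = _unit(np.asarray(palm_normal, dtype=float), "palm_normal")
    cos_view = abs(float(camera.view_direction() @ n_palm))
    base = noise.confidence_base * cos_view**noise.confidence_view_exponent

    n = trace.n_frames
    conf = base + noise.confidence_noise_sd * rng.standard_normal(n)
    conf = np.clip(conf, 0.0, 1.0)
    detected = conf >= noise.dropout_threshold

    if trace.space in (Space.PIXEL, Space.NORMALIZED):
        sd = np.array([noise.jitter_sd_px] * trace.n_axes)
    else:
        sd_mm = noise.jitter_sd_mm
        sd = np.array([sd_mm] * trace.n_axes) * (0.001 if trace.space is Space.WORLD_M else 1.0)
    if trace.n_axes == 3:
        sd[2] *= noise.depth_jitter_factor
    if trace.space is Space.NORMALIZED:
        w, h = trace.frame_resolution  # type: ignore[misc]
        sd = sd / np.array([w, h, w][: trace.n_axes])

    jitter = _ar1_noise(rng, trace.positions.shape, noise.jitter_ar1) * sd
    positions = trace.positions + jitter
    if trace.n_axes == 3 and noise.depth_scale_noise_cv > 0:
        gain = 1.0 + _smooth_noise(rng, trace.timestamps, noise.depth_scale_noise_cv)
        positions[..., 2] *= gain[:, None]
    positions[~detected] = np.nan

    return trace.replace(positions=positions, confidence=conf, detected=detected)


def synthesize_imu(
    world_trace: TrajectoryTrace,
    noise_sd: float = 0.1,
    seed: int = 0,
    sample_rate: float = 200.0,
) -> ImuSeries:
    """Accelerometer series from the palm trajectory (gravity included).

    The palm position (mean of wrist and knuckle landmarks, metres) is
    resampled to the IMU rate; acceleration is its second central finite
    difference plus the static gravity reaction and white noise.
    """
    if world_trace.space not in (Space.WORLD_MM, Space.WORLD_M):
        raise ConfigError("synthesize_imu requires a world-space trace")
    if world_trace.sample_rate < sample_rate / 4:
        raise ConfigError("world trace too sparse to resample to the IMU rate")
    scale = 0.001 if world_trace.space is Space.WORLD_MM else 1.0
    idx = [world_trace.landmark_index(l) for l in _PALM_LANDMARKS if l in world_trace.landmark_ids]
    palm = world_trace.positions[:, idx, :].mean(axis=1) * scale  # (T, 3) m

    t_imu = np.arange(0.0, world_trace.timestamps[-1], 1.0 / sample_rate)
    # cubic-spline resampling: a C2 interpolant is required because the
    # acceleration is a second difference (linear interpolation would turn
    # the source sample knots into impulses)
    spline = CubicSpline(world_trace.timestamps, palm, axis=0)
    p = spline(t_imu)
    dt = 1.0 / sample_rate
    acc = np.empty_like(p)
    acc[1:-1] = (p[2:] - 2 * p[1:-1] + p[:-2]) / dt**2
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    acc[:, 2] += _GRAVITY_MS2  # specific force of a static sensor reads +g
    rng = np.random.default_rng(seed)
    acc = acc + noise_sd * rng.standard_normal(acc.shape)
    return ImuSeries(timestamps=t_imu, accel=acc, sample_rate=sample_rate)


@dataclass
class SyntheticScene:
    """Co-registered synthetic recording: all traces share one time origin."""

    config: SimConfig
    camera: CameraModel
    noise: NoiseModel
    world_truth: TrajectoryTrace
    true_amplitude_envelope: np.ndarray  # half-amplitude, mm, per world frame
    omc: TrajectoryTrace
    mp_norm: TrajectoryTrace
    mp_world: TrajectoryTrace
    vi_pixel: TrajectoryTrace
    imu: ImuSeries
    marker_extent_px: np.ndarray  # (frames, 2)

    def trace_for(self, variant) -> TrajectoryTrace:
        return {"mp_norm": self.mp_norm, "mp_world": self.mp_world,
                "vi_pixel": self.vi_pixel, "omc": self.omc}[variant.trace_key]


def _child_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31))


def build_scene(
    config: SimConfig,
    camera: CameraModel | None = None,
    noise: NoiseModel | None = None,
    omc_sample_rate: float = 100.0,
    omc_jitter_sd_mm: float = 0.05,
    imu_noise_sd: float = 0.1,
) -> SyntheticScene:
    """Full synthetic recording for one subject/viewpoint.

    Emulated outputs: frame-normalized landmarks with pseudo-depth
    (``mp_norm``), camera-aligned metric landmarks about the rest centroid in
    metres with scale noise (``mp_world``), pixel landmarks without depth
    (``vi_pixel``), a down-sampled low-noise metric trace of three fiducial
    landmarks (``omc``), and a palm accelerometer (``imu``).
    """
    camera = camera or CameraModel()
    noise = noise or NoiseModel()
    world, envelope = simulate_hand_trajectory(config)
    seq = np.random.SeedSequence([config.seed, noise.seed, 0x7C_AD])
    s_vi, s_mp, s_world, s_omc, s_imu, s_scale = (_child_seed(c) for c in seq.spawn(6))

    proj = project_to_camera(world, camera)
    vi_pixel = apply_tracking_noise(proj.trace, noise, camera, config.palm_normal, seed=s_vi)
    mp_pixel3 = append_depth_channel(proj, camera)
    mp_norm = normalize_to_frame(apply_tracking_noise(mp_pixel3, noise, camera, config.palm_normal, seed=s_mp))

    # camera-aligned metric landmarks about the rest centroid ("2.5D" world output)
    centroid = world.positions.reshape(-1, 3).mean(axis=0)
    cam_m = ((world.positions - centroid) / 1000.0) @ camera.rotation().T
    rng_scale = np.random.default_rng(s_scale)
    gain = 1.0 + _smooth_noise(rng_scale, world.timestamps, noise.world_scale_noise_cv)
    mp_world_clean = world.replace(positions=cam_m * gain[:, None, None], space=Space.WORLD_M)
    mp_world = apply_tracking_noise(mp_world_clean, noise, camera, config.palm_normal, seed=s_world)

    # marker-based optical capture: landmarks 4/9/12 at its own rate, tiny noise
    rng_omc = np.random.default_rng(s_omc)
    t_omc = np.arange(0.0, config.duration_s, 1.0 / omc_sample_rate)
    omc_ids = [4, 9, MIDDLE_FINGERTIP]
    omc_pos = np.empty((t_omc.size, len(omc_ids), 3))
    for j, lm in enumerate(omc_ids):
        src = world.landmark(lm)
        for a in range(3):
            omc_pos[:, j, a] = np.interp(t_omc, world.timestamps, src[:, a])
    omc_pos += omc_jitter_sd_mm * rng_omc.standard_normal(omc_pos.shape)
    omc = TrajectoryTrace(
        timestamps=t_omc,
        positions=omc_pos,
        space=Space.WORLD_MM,
        landmark_ids=np.array(omc_ids),
        confidence=np.ones(t_omc.size),
        detected=np.ones(t_omc.size, dtype=bool),
        sample_rate=omc_sample_rate,
    )

    imu = synthesize_imu(world, noise_sd=imu_noise_sd, seed=s_imu)
    return SyntheticScene(
        config=config, camera=camera, noise=noise,
        world_truth=world, true_amplitude_envelope=envelope,
        omc=omc, mp_norm=mp_norm, mp_world=mp_world, vi_pixel=vi_pixel,
        imu=imu, marker_extent_px=proj.marker_extent_px,
    )


def tetras_from_amplitude(
    peak_to_peak_mm: float,
    thresholds: Sequence[tuple[float, float]] | None = None,
) -> float:
    """Ordinal severity score (0–5, half steps) from peak-to-peak amplitude."""
    if peak_to_peak_mm < 0:
        raise ConfigError("amplitude must be non-negative")
    table = DEFAULT_TETRAS_THRESHOLDS if thresholds is None else tuple(thresholds)
    score = 0.0
    for lower, s in table:
        if peak_to_peak_mm >= lower:
            score = s
    return score


@dataclass
class CohortSubject:
    """One synthetic subject: a scene plus its clinical-style annotations."""

    subject_id: int
    scene: SyntheticScene
    true_peak_to_peak_mm: float
    true_frequency_hz: float
    tetras_score: float
    tremor_type: str  # "rest" | "postural"


def synthesize_cohort(
    n_subjects: int = 20,
    amplitude_range_mm: tuple[float, float] = (1.0, 100.0),
    frequency_range_hz: tuple[float, float] = (3.5, 7.5),
    tetras_map: Sequence[tuple[float, float]] | None = None,
    seed: int = 0,
    camera: CameraModel | None = None,
    noise: NoiseModel | None = None,
    duration_s: float = 30.0,
) -> list[CohortSubject]:
    """Seeded stand-in for a clinical validation cohort.

    Peak-to-peak amplitudes are log-uniform over ``amplitude_range_mm`` (the
    perceived severity of tremor scales logarithmically), frequencies uniform
    over ``frequency_range_hz``; each subject's ordinal severity score comes
    from the configurable threshold map.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    lo, hi = float(amplitude_range_mm[0]), float(amplitude_range_mm[1])
    flo, fhi = float(frequency_range_hz[0]), float(frequency_range_hz[1])
    if not 0 < lo <= hi or not 0 < flo <= fhi:
        raise ConfigError("empty or non-positive parameter range")
    camera = camera or CameraModel()
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        p2p = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        f = rng.uniform(flo, fhi)
        tremor_type = "rest" if rng.random() < 0.35 else "postural"
        cfg = SimConfig(
            tremor_frequency_hz=f,
            amplitude_start_mm=p2p / 2.0,
            duration_s=duration_s,
            seed=int(rng.integers(2**31)),
        )
        nz = replace(noise or NoiseModel(), seed=int(rng.integers(2**31)))
        scene = build_scene(cfg, camera=camera, noise=nz)
        subjects.append(
            CohortSubject(
                subject_id=i + 1,
                scene=scene,
                true_peak_to_peak_mm=p2p,
                true_frequency_hz=f,
                tetras_score=tetras_from_amplitude(p2p, tetras_map),
                tremor_type=tremor_type,
            )
        )
    return subjects
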