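"""Core data model for landmark and accelerometer time series.

A :class:`TrajectoryTrace` is the universal currency between all stages of the
pipeline: per-frame positions of up to 21 hand landmarks in one of four
coordinate spaces, with a per-frame tracking confidence and a detection flag.
Undetected frames carry ``NaN`` positions end to end; any interpolation across
them is an explicit downstream step, never implicit.

Landmark numbering follows the common 21-point hand topology (0 = wrist,
4 = thumb tip, 9 = middle-finger MCP, 12 = middle fingertip); the analysis
stages only ever read landmark 12.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import TraceValidationError

__all__ = [
    "Space",
    "MethodVariant",
    "TrajectoryTrace",
    "ImuSeries",
    "MIDDLE_FINGERTIP",
]

#: Landmark id of the middle fingertip, the sole point the pipeline analyzes.
MIDDLE_FINGERTIP = 12


class Space(str, enum.Enum):
    """Coordinate space of a trace."""

    WORLD_MM = "world_mm"  #: metric 3D, millimetres (OMC-style, and ground truth)
    WORLD_M = "world_m"  #: metric 3D, metres (MP-world-style)
    PIXEL = "pixel"  #: image coordinates, origin top-left, y down
    NORMALIZED = "normalized"  #: pixel / (width, height); z scaled like x


class MethodVariant(enum.Enum):
    """Which trace and which axes enter the displacement computation.

    The x/y-only variants mirror the practice of dropping the estimated depth
    channel, which is a coarse "2.5D" reconstruction for the normalized and
    world landmark outputs.
    """

    MP_WORLD_XY = ("mp_world", (0, 1))
    MP_WORLD_XYZ = ("mp_world", (0, 1, 2))
    MP_NORM_XY = ("mp_norm", (0, 1))
    MP_NORM_XYZ = ("mp_norm", (0, 1, 2))
    VI_XY = ("vi_pixel", (0, 1))
    OMC_XYZ = ("omc", (0, 1, 2))

    def __init__(self, trace_key: str, axes: tuple[int, ...]):
        self.trace_key = trace_key
        self.axes = axes

    @property
    def uses_z(self) -> bool:
        return 2 in self.axes

    @property
    def spectral_axes(self) -> tuple[int, ...]:
        """Axes admitted into spectral peak detection.

        Camera-derived traces contribute x and y only (the depth channel is
        too noisy to help); metric motion-capture traces use all three.
        """
        return (0, 1, 2) if self is MethodVariant.OMC_XYZ else (0, 1)


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise TraceValidationError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class TrajectoryTrace:
    """Per-frame landmark positions with confidence and detection flags.

    Parameters
    ----------
    timestamps
        Seconds, strictly increasing, one per frame.
    positions
        ``(frames, landmarks, axes)`` with axes ``(x, y)`` or ``(x, y, z)``;
        ``NaN`` wherever ``detected`` is False.
    space
        Coordinate space of ``positions``.
    landmark_ids
        Integer ids (0–20) of the landmark axis, in storage order.
    confidence
        Per-frame tracking confidence in [0, 1].
    detected
        Per-frame boolean detection flag.
    sample_rate
        Nominal sampling rate in Hz.
    frame_resolution
        ``(width, height)`` in pixels; required for pixel/normalized spaces.
    """

    timestamps: np.ndarray
    positions: np.ndarray
    space: Space
    landmark_ids: np.ndarray
    confidence: np.ndarray
    detected: np.ndarray
    sample_rate: float
    frame_resolution: tuple[int, int] | None = None

    def __post_init__(self):
        self.timestamps = _as_float_array(self.timestamps, "timestamps", 1)
        self.positions = _as_float_array(self.positions, "positions", 3)
        self.space = Space(self.space)
        self.landmark_ids = np.asarray(self.landmark_ids, dtype=int)
        self.confidence = _as_float_array(self.confidence, "confidence", 1)
        self.detected = np.asarray(self.detected, dtype=bool)
        self.sample_rate = float(self.sample_rate)

        n = self.timestamps.size
        if self.positions.shape[0] != n or self.confidence.size != n or self.detected.size != n:
            raise TraceValidationError("frame-count mismatch between fields")
        if self.positions.shape[1] != self.landmark_ids.size:
            raise TraceValidationError("landmark-count mismatch")
        if self.positions.shape[2] not in (2, 3):
            raise TraceValidationError("positions must have 2 or 3 axes")
        if n >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise TraceValidationError("timestamps must be strictly increasing")
        if self.sample_rate <= 0:
            raise TraceValidationError("sample_rate must be positive")
        if np.any((self.confidence < -1e-9) | (self.confidence > 1 + 1e-9)):
            raise TraceValidationError("confidence must lie in [0, 1]")
        if not np.all(np.isfinite(self.positions[self.detected])):
            raise TraceValidationError("positions must be finite on detected frames")
        if self.space in (Space.PIXEL, Space.NORMALIZED):
            if self.frame_resolution is None:
                raise TraceValidationError(f"frame_resolution required for {self.space.value} space")
            self.frame_resolution = (int(self.frame_resolution[0]), int(self.frame_resolution[1]))
        if self.space is Space.NORMALIZED and self.detected.any():
            xy = self.positions[self.detected][:, :, :2]
            if np.any((xy < -0.5) | (xy > 1.5)):
                raise TraceValidationError("normalized coordinates of detected frames outside [-0.5, 1.5]")

    # -- basic introspection -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.timestamps.size

    @property
    def n_axes(self) -> int:
        return self.positions.shape[2]

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def detected_fraction(self) -> float:
        return float(self.detected.mean()) if self.n_frames else 0.0

    def landmark_index(self, landmark_id: int) -> int:
        hits = np.flatnonzero(self.landmark_ids == landmark_id)
        if hits.size == 0:
            raise TraceValidationError(f"landmark {landmark_id} not present in trace")
        return int(hits[0])

    def landmark(self, landmark_id: int) -> np.ndarray:
        """Positions of one landmark, shape ``(frames, axes)``."""
        return self.positions[:, self.landmark_index(landmark_id), :]

    def replace(self, **kwargs) -> "TrajectoryTrace":
        return dataclasses.replace(self, **kwargs)

    # -- space conversions ---------------------------------------------------

    def to_normalized(self) -> "TrajectoryTrace":
        """Pixel → normalized; inverse of :meth:`to_pixel` to float precision.

        x (and the depth channel, if present) divide by frame width, y by
        frame height, matching the convention that the depth estimate is
        scaled like x.
        """
        if self.space is Space.NORMALIZED:
            return self
        if self.space is not Space.PIXEL:
            raise TraceValidationError("to_normalized requires a pixel-space trace")
        w, h = self.frame_resolution  # type: ignore[misc]
        scale = np.array([w, h, w][: self.n_axes], dtype=float)
        return self.replace(positions=self.positions / scale, space=Space.NORMALIZED)

    def to_pixel(self) -> "TrajectoryTrace":
        """Normalized → pixel; inverse of :meth:`to_normalized` to float precision."""
        if self.space is Space.PIXEL:
            return self
        if self.space is not Space.NORMALIZED:
            raise TraceValidationError("to_pixel requires a normalized-space trace")
        w, h = self.frame_resolution  # type: ignore[misc]
        scale = np.array([w, h, w][: self.n_axes], dtype=float)
        return self.replace(positions=self.positions * scale, space=Space.PIXEL)

    # -- gap structure -------------------------------------------------------

    def detected_segments(self, max_gap_s: float = 0.25) -> list[tuple[int, int]]:
        """Half-open frame ranges of usable data.

        Undetected edges are trimmed; interior undetected runs no longer than
        ``max_gap_s`` stay inside a segment (to be interpolated by the
        caller), longer runs split the trace.
        """
        det = self.detected
        if not det.any():
            return []
        idx = np.flatnonzero(det)
        max_gap = int(round(max_gap_s * self.sample_rate))
        segments: list[tuple[int, int]] = []
        start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i - prev - 1 > max_gap:
                segments.append((int(start), int(prev) + 1))
                start = i
            prev = i
        segments.append((int(start), int(prev) + 1))
        return segments

    def interpolated_positions(self, landmark_id: int, start: int, stop: int) -> np.ndarray:
        """Positions of one landmark over ``[start, stop)`` with interior
        undetected frames filled by linear interpolation in time."""
        pos = self.landmark(landmark_id)[start:stop].copy()
        det = self.detected[start:stop]
        if det.all():
            return pos
        t = self.timestamps[start:stop]
        good = np.flatnonzero(det)
        if good.size < 2:
            raise TraceValidationError("segment has fewer than 2 detected frames")
        for ax in range(pos.shape[1]):
            pos[:, ax] = np.interp(t, t[good], pos[good, ax])
        return pos


@dataclass
class ImuSeries:
    """Tri-axial accelerometer series (m/s², gravity included)."""

    timestamps: np.ndarray
    accel: np.ndarray  # (frames, 3)
    sample_rate: float

    def __post_init__(self):
        self.timestamps = _as_float_array(self.timestamps, "timestamps", 1)
        self.accel = _as_float_array(self.accel, "accel", 2)
        self.sample_rate = float(self.sample_rate)
        if self.accel.shape != (self.timestamps.size, 3):
            raise TraceValidationError("accel must have shape (frames, 3)")
        if self.timestamps.size >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise TraceValidationError("timestamps must be strictly increasing")


def infer_sample_rate(timestamps: Sequence[float]) -> float:
    """Sampling rate from the median spacing of a (nearly) uniform grid."""
    t = np.asarray(timestamps, dtype=float)
    if t.size < 2:
        raise TraceValidationError("need at least 2 timestamps to infer a sample rate")
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise TraceValidationError("non-increasing timestamps")
    return 1.0 / dt
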