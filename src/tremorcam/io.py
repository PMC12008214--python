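"""Readers and writers for landmark, motion-capture, and accelerometer series.

Canonical on-disk formats are plain text:

* **trajectory CSV** (wide): ``time_s, lm{NN}_x, lm{NN}_y[, lm{NN}_z], …,
  confidence, detected`` with a JSON sidecar ``<name>.meta.json`` carrying
  the coordinate space, sample rate and frame resolution.  Undetected frames
  have empty position cells, never zeros.
* **marker TSV**: the same wide layout, tab-separated, metric 3D positions;
  confidence/detected columns are optional and default to fully detected.
* **trajectory JSON**: a single self-describing document (used for
  machine-readable reports).
* **IMU CSV**: ``time_s, ax, ay, az`` in m/s².

All readers validate and reject malformed input with named errors rather
than silently coercing it.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    BackendUnavailableError,
    FormatError,
    MissingColumnsError,
    MixedAxesError,
    NonMonotonicTimestampsError,
)
from .trace import ImuSeries, Space, TrajectoryTrace, infer_sample_rate

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_imu",
    "write_imu",
    "extract_landmarks_from_video",
]

_LM_COL = re.compile(r"^lm(\d{1,2})_([xyz])$")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_trajectory(trace: TrajectoryTrace, path) -> Path:
    """Write the canonical wide CSV plus its JSON metadata sidecar."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {"time_s": trace.timestamps}
    axis_names = "xyz"[: trace.n_axes]
    for j, lm in enumerate(trace.landmark_ids):
        for a, name in enumerate(axis_names):
            cols[f"lm{int(lm):02d}_{name}"] = trace.positions[:, j, a]
    cols["confidence"] = trace.confidence
    cols["detected"] = trace.detected.astype(int)
    # %.17g guarantees bit-exact float64 round trips through the text format
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "schema": "tremorcam-trajectory-v1",
        "space": trace.space.value,
        "sample_rate_hz": trace.sample_rate,
        "frame_resolution_px": list(trace.frame_resolution) if trace.frame_resolution else None,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _parse_landmark_columns(columns) -> tuple[list[int], int, dict[tuple[int, str], str]]:
    by_lm: dict[int, set[str]] = {}
    colmap: dict[tuple[int, str], str] = {}
    for c in columns:
        m = _LM_COL.match(c)
        if m:
            lm, axis = int(m.group(1)), m.group(2)
            by_lm.setdefault(lm, set()).add(axis)
            colmap[(lm, axis)] = c
    if not by_lm:
        raise MissingColumnsError("no landmark columns (lmNN_x/y/z) found")
    axis_counts = {frozenset(v) for v in by_lm.values()}
    if len(axis_counts) > 1:
        raise MixedAxesError("landmarks carry inconsistent axis sets")
    axes = axis_counts.pop()
    if axes not in ({"x", "y"}, {"x", "y", "z"}):
        raise MixedAxesError(f"unsupported axis set {sorted(axes)}")
    return sorted(by_lm), len(axes), colmap


def _frame_from_table(df: pd.DataFrame, meta: dict, require_flags: bool) -> TrajectoryTrace:
    if "time_s" not in df.columns:
        raise MissingColumnsError("missing required column time_s")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise NonMonotonicTimestampsError("time_s must be strictly increasing")
    lm_ids, n_axes, colmap = _parse_landmark_columns(df.columns)
    positions = np.empty((t.size, len(lm_ids), n_axes))
    for j, lm in enumerate(lm_ids):
        for a, name in enumerate("xyz"[:n_axes]):
            positions[:, j, a] = df[colmap[(lm, name)]].to_numpy(dtype=float)
    if require_flags and not {"confidence", "detected"} <= set(df.columns):
        raise MissingColumnsError("missing confidence/detected columns")
    if "detected" in df.columns:
        detected = df["detected"].to_numpy(dtype=float).astype(bool)
    else:
        detected = np.all(np.isfinite(positions.reshape(t.size, -1)), axis=1)
    confidence = (df["confidence"].to_numpy(dtype=float)
                  if "confidence" in df.columns else np.ones(t.size))
    positions[~detected] = np.nan

    sample_rate = meta.get("sample_rate_hz") or infer_sample_rate(t)
    resolution = meta.get("frame_resolution_px")
    return TrajectoryTrace(
        timestamps=t,
        positions=positions,
        space=Space(meta.get("space", Space.WORLD_MM.value)),
        landmark_ids=np.array(lm_ids),
        confidence=confidence,
        detected=detected,
        sample_rate=float(sample_rate),
        frame_resolution=tuple(resolution) if resolution else None,
    )


def read_trajectory(path, format_hint: str | None = None) -> TrajectoryTrace:
    """Read a trajectory from CSV (wide), marker TSV, or JSON document.

    The format is taken from ``format_hint`` (``"csv"``, ``"omc_tsv"``,
    ``"json"``) or inferred from the file suffix.  CSV reads pick up the
    JSON metadata sidecar when present; the sample rate falls back to the
    median timestamp spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format_hint or {".json": "json", ".tsv": "omc_tsv"}.get(path.suffix.lower(), "csv")
    if fmt == "json":
        return _trajectory_from_json(json.loads(path.read_text()))
    sep = "\t" if fmt == "omc_tsv" else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if fmt == "csv" and sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return _frame_from_table(df, meta, require_flags=(fmt == "csv"))


def trajectory_to_json(trace: TrajectoryTrace) -> dict:
    def _nanlist(a: np.ndarray) -> list:
        return np.where(np.isfinite(a), a, None).tolist()

    return {
        "schema": "tremorcam-trajectory-v1",
        "space": trace.space.value,
        "sample_rate_hz": trace.sample_rate,
        "frame_resolution_px": list(trace.frame_resolution) if trace.frame_resolution else None,
        "landmark_ids": trace.landmark_ids.tolist(),
        "timestamps_s": trace.timestamps.tolist(),
        "positions": _nanlist(trace.positions),
        "confidence": trace.confidence.tolist(),
        "detected": trace.detected.astype(bool).tolist(),
    }


def _trajectory_from_json(doc: dict) -> TrajectoryTrace:
    try:
        positions = np.array(
            [[[np.nan if v is None else float(v) for v in ax] for ax in frame]
             for frame in doc["positions"]], dtype=float)
        resolution = doc.get("frame_resolution_px")
        return TrajectoryTrace(
            timestamps=np.asarray(doc["timestamps_s"], dtype=float),
            positions=positions,
            space=Space(doc["space"]),
            landmark_ids=np.asarray(doc["landmark_ids"], dtype=int),
            confidence=np.asarray(doc["confidence"], dtype=float),
            detected=np.asarray(doc["detected"], dtype=bool),
            sample_rate=float(doc["sample_rate_hz"]),
            frame_resolution=tuple(resolution) if resolution else None,
        )
    except KeyError as exc:
        raise MissingColumnsError(f"trajectory JSON missing field {exc}") from exc


def write_trajectory_json(trace: TrajectoryTrace, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(trajectory_to_json(trace)))
    return path


def write_imu(imu: ImuSeries, path) -> Path:
    """Write the 4-column accelerometer CSV (time_s, ax, ay, az)."""
    path = Path(path)
    pd.DataFrame({
        "time_s": imu.timestamps,
        "ax": imu.accel[:, 0], "ay": imu.accel[:, 1], "az": imu.accel[:, 2],
    }).to_csv(path, index=False, float_format="%.17g")
    return path


def read_imu(path) -> ImuSeries:
    """Read the 4-column accelerometer CSV."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time_s", "ax", "ay", "az"} - set(df.columns)
    if missing:
        raise MissingColumnsError(f"IMU file missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise NonMonotonicTimestampsError("time_s must be strictly increasing")
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    return ImuSeries(timestamps=t, accel=accel, sample_rate=infer_sample_rate(t))


def extract_landmarks_from_video(path, backend: str = "mediapipe") -> TrajectoryTrace:
    """Optional adapter: run an external hand-tracking backend on a video.

    The backend (``mediapipe``) is an optional dependency; when it is not
    installed this degrades to a named :class:`BackendUnavailableError`
    rather than an import failure.  The package's correctness never depends
    on this adapter — it exists so recorded videos can be brought into the
    canonical trace format.
    """
    if backend != "mediapipe":
        raise BackendUnavailableError(f"unknown backend {backend!r}")
    try:
        import cv2  # type: ignore
        import mediapipe as mp  # type: ignore
    except ImportError as exc:
        raise BackendUnavailableError(
            "hand-tracking backend unavailable: install the 'video' extra "
            "(opencv-python + mediapipe)") from exc

    cap = cv2.VideoCapture(str(path))
    if not cap.isOpened():
        raise FormatError(f"unreadable video: {path}")
    fps = cap.get(cv2.CAP_PROP_FPS) or 30.0
    width = int(cap.get(cv2.CAP_PROP_FRAME_WIDTH))
    height = int(cap.get(cv2.CAP_PROP_FRAME_HEIGHT))
    hands = mp.solutions.hands.Hands(static_image_mode=False, max_num_hands=1)
    frames, confs, det = [], [], []
    while True:
        ok, frame = cap.read()
        if not ok:
            break
        result = hands.process(cv2.cvtColor(frame, cv2.COLOR_BGR2RGB))
        if result.multi_hand_landmarks:
            lms = result.multi_hand_landmarks[0].landmark
            frames.append([[p.x, p.y, p.z] for p in lms])
            score = result.multi_handedness[0].classification[0].score if result.multi_handedness else 1.0
            confs.append(float(score))
            det.append(True)
        else:
            frames.append([[np.nan] * 3] * 21)
            confs.append(0.0)
            det.append(False)
    cap.release()
    if not any(det):
        raise FormatError(f"no hand detected in any frame of {path}")
    n = len(frames)
    return TrajectoryTrace(
        timestamps=np.arange(n) / fps,
        positions=np.asarray(frames, dtype=float),
        space=Space.NORMALIZED,
        landmark_ids=np.arange(21),
        confidence=np.asarray(confs),
        detected=np.asarray(det, dtype=bool),
        sample_rate=float(fps),
        frame_resolution=(width, height),
    )
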