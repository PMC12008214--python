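import numpy as np
import pytest

from tremorcam import (
    CameraModel,
    NoiseModel,
    SimConfig,
    Space,
    TrajectoryTrace,
    build_scene,
)

FS = 120.0


def make_trace(positions_1lm: np.ndarray, fs: float = FS, space: Space = Space.WORLD_MM,
               landmark_id: int = 12, detected: np.ndarray | None = None,
               resolution: tuple[int, int] | None = None) -> TrajectoryTrace:
    """Single-landmark trace from an (n, axes) position array."""
    pos = np.asarray(positions_1lm, dtype=float)
    if pos.ndim == 1:
        pos = pos[:, None]
    if pos.shape[1] == 1:
        pos = np.column_stack([pos, np.zeros((pos.shape[0], 2))])
    elif pos.shape[1] == 2:
        pos = np.column_stack([pos, np.zeros(pos.shape[0])])
    n = pos.shape[0]
    det = np.ones(n, dtype=bool) if detected is None else np.asarray(detected, dtype=bool)
    pos = pos[:, None, :].copy()
    pos[~det] = np.nan
    return TrajectoryTrace(
        timestamps=np.arange(n) / fs,
        positions=pos,
        space=space,
        landmark_ids=np.array([landmark_id]),
        confidence=det.astype(float),
        detected=det,
        sample_rate=fs,
        frame_resolution=resolution,
    )


def sinusoid(amplitude: float, frequency: float, duration: float = 30.0,
             fs: float = FS, phase: float = 0.0) -> np.ndarray:
    t = np.arange(0, duration, 1 / fs)
    return amplitude * np.sin(2 * np.pi * frequency * t + phase)


@pytest.fixture(scope="session")
def default_scene():
    """6 Hz, 10 mm half-amplitude, default camera (45° above) and noise."""
    return build_scene(SimConfig(seed=3), noise=NoiseModel(seed=4))


@pytest.fixture(scope="session")
def topdown_inplane_scene():
    """Tremor in the image plane viewed straight top-down (best geometry)."""
    return build_scene(
        SimConfig(tremor_axis=(1.0, 0.0, 0.0), amplitude_start_mm=10.0, seed=3),
        camera=CameraModel(elevation_deg=-90.0),
        noise=NoiseModel(seed=11),
    )
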