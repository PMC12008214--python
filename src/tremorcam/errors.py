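"""Exception hierarchy.

Every reader and estimator rejects malformed input with a named error from
this module rather than silently coercing it; "amplitude not estimable" is a
first-class outcome (:class:`NotEstimableError`), not a generic failure.
"""

from __future__ import annotations


class TremorAnalysisError(Exception):
    """Base class for all package errors."""


class ConfigError(TremorAnalysisError, ValueError):
    """Invalid or non-finite configuration field."""


class TraceValidationError(TremorAnalysisError, ValueError):
    """A trajectory trace violates its structural invariants."""


class FormatError(TremorAnalysisError, ValueError):
    """Malformed on-disk data."""


class NonMonotonicTimestampsError(FormatError):
    """Timestamps are not strictly increasing."""


class MissingColumnsError(FormatError):
    """A required column is absent from the file."""


class MixedAxesError(FormatError):
    """Landmarks carry inconsistent axis counts (some x/y, some x/y/z)."""


class InvalidBandError(TremorAnalysisError, ValueError):
    """Band edges violate 0 < low < high < Nyquist."""


class SeriesTooShortError(TremorAnalysisError, ValueError):
    """Series too short for the requested filter or spectral segment."""


class NotEstimableError(TremorAnalysisError, RuntimeError):
    """Amplitude could not be estimated (too few detected frames or no
    oscillation reversals in the pass band)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class DegenerateDataError(TremorAnalysisError, ValueError):
    """Statistic undefined on the given data (e.g. all-tied ranks)."""


class TooFewSubjectsError(TremorAnalysisError, ValueError):
    """Too few paired subjects for a group comparison."""


class BehindCameraError(TremorAnalysisError, ValueError):
    """A world point fell on or behind the camera plane."""

    def __init__(self, frame_index: int):
        super().__init__(f"point behind camera at frame {frame_index}")
        self.frame_index = frame_index


class BackendUnavailableError(TremorAnalysisError, RuntimeError):
    """Optional hand-tracking backend is not installed."""


class DataUnavailableError(TremorAnalysisError, RuntimeError):
    """An optional external dataset is not present locally."""
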