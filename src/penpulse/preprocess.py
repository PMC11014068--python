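"""Magnitude fusion and detrending of triaxial recordings.

The pipeline works on a single channel: the Euclidean magnitude
``a = sqrt(ax² + ay² + az²)`` of the three accelerometer axes.  The
magnitude is orientation-free, which matters for a hand-held pen whose
attitude is never controlled precisely.  A resting grip leaves the
magnitude sitting near 1 g (gravity); removing that offset before
filtering and peak detection makes peak prominences comparable across
recordings, so mean-removal is the default, with a moving-mean variant
for slowly drifting grips.  Detrending can be skipped entirely to run
the magnitude → low-pass → peaks chain on the raw offset signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import DataError, ParameterError
from .io import AccelRecording

STAGES = ("raw_magnitude", "detrended", "filtered")


@dataclass(eq=False)
class MagnitudeTrace:
    """Single-channel acceleration trace on the recording's time base.

    ``stage`` tracks provenance through the pipeline: ``raw_magnitude``
    (non-negative Euclidean magnitude), ``detrended`` (offset removed),
    or ``filtered`` (low-pass applied).
    """

    t: np.ndarray
    a: np.ndarray
    fs: float
    stage: str = "raw_magnitude"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.stage not in STAGES:
            raise ParameterError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.t.size != self.a.size:
            raise DataError(f"length mismatch: t has {self.t.size}, a has {self.a.size}")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise DataError("time not strictly increasing")
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if self.stage == "raw_magnitude" and self.a.size and float(np.min(self.a)) < 0:
            raise DataError("raw magnitude cannot be negative")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size >= 2 else 0.0


def magnitude(rec: AccelRecording) -> MagnitudeTrace:
    """Euclidean magnitude of the three axes, in g."""
    a = np.sqrt(rec.ax**2 + rec.ay**2 + rec.az**2)
    return MagnitudeTrace(t=rec.t, a=a, fs=rec.fs, stage="raw_magnitude")


def detrend(
    trace: MagnitudeTrace,
    method: str = "mean",
    window: float | None = None,
) -> MagnitudeTrace:
    """Remove the quasi-static (gravity) offset from a magnitude trace.

    Parameters
    ----------
    method : {"mean", "median", "moving_mean"}
        ``mean``/``median`` subtract one global statistic;
        ``moving_mean`` subtracts a centred moving average of ``window``
        seconds, which tracks slow grip drift.
    window : float, optional
        Moving-average length in seconds; required for ``moving_mean``.
    """
    if trace.stage == "filtered":
        raise ParameterError("detrend expects a raw_magnitude or detrended trace")
    a = trace.a
    if method == "mean":
        baseline = np.mean(a)
    elif method == "median":
        baseline = np.median(a)
    elif method == "moving_mean":
        if window is None:
            raise ParameterError("moving_mean detrending requires a window length in seconds")
        size = int(round(window * trace.fs))
        if size < 1:
            raise ParameterError(f"window {window} s is shorter than one sample at {trace.fs} Hz")
        if size > a.size:
            raise ParameterError(
                f"window {window} s ({size} samples) exceeds trace length ({a.size} samples)"
            )
        if size == a.size:  # limiting case: moving mean degenerates to the global mean
            baseline = np.mean(a)
        else:
            baseline = uniform_filter1d(a, size=size, mode="nearest")
    else:
        raise ParameterError(f"unknown detrend method {method!r}")
    return replace(trace, a=a - baseline, stage="detrended")
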