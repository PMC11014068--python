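"""Readers and writers for recordings, beat-event logs and agreement reports.

File conventions
----------------
All signal files are delimited text (comma by default) with a single
header line.  A pen recording holds raw accelerometer counts in columns
``ax, ay, az`` plus an optional time column ``t`` in seconds; when the
time column is absent the sample clock is reconstructed as
``t = index / fs``.  Beat-event logs hold a single column which is either
beat timestamps in seconds or successive RR intervals (dialect selected by
the caller).  Agreement reports are JSON.

Counts are converted to units of g through a :class:`ScaleConfig`.  The
default corresponds to an LSM6DSL-class MEMS accelerometer configured at
±2 g full scale (16384 counts per g); vendors vary, so every field is
overridable from the run configuration.

Each file starts its own clock: cross-device alignment is the agreement
module's job, never the reader's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ParameterError

_AXIS_COLUMNS = ("ax", "ay", "az")


@dataclass(frozen=True)
class ScaleConfig:
    """Affine conversion between raw sensor counts and acceleration in g.

    Parameters
    ----------
    full_scale : float
        Configured accelerometer range in g (metadata only; the
        conversion is fully determined by ``counts_per_g`` and
        ``offset_counts``).
    counts_per_g : float
        Raw counts corresponding to 1 g.
    offset_counts : float
        Zero-g offset in counts, subtracted before scaling.
    """

    full_scale: float = 2.0
    counts_per_g: float = 16384.0
    offset_counts: float = 0.0

    def __post_init__(self) -> None:
        if not self.counts_per_g > 0:
            raise ParameterError(f"counts_per_g must be positive, got {self.counts_per_g}")

    @property
    def quantization_step(self) -> float:
        """Smallest representable acceleration difference, in g."""
        return 1.0 / self.counts_per_g

    def to_g(self, counts) -> np.ndarray:
        return (np.asarray(counts, dtype=float) - self.offset_counts) / self.counts_per_g

    def to_counts(self, accel_g) -> np.ndarray:
        counts = np.asarray(accel_g, dtype=float) * self.counts_per_g + self.offset_counts
        return np.rint(counts).astype(np.int64)

    def quantize(self, accel_g) -> np.ndarray:
        """Round acceleration to the sensor's count grid, staying in g."""
        return self.to_g(self.to_counts(accel_g))


@dataclass(eq=False)
class AccelRecording:
    """Uniformly sampled triaxial acceleration trace in units of g.

    Invariants: all four arrays share a length of at least two, ``t`` is
    strictly increasing and deviates from the nominal ``1/fs`` grid by
    less than ``time_tol`` seconds per step.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)
    time_tol: float = 1e-3

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = self.t.size
        if n < 2:
            raise DataError(f"recording needs at least 2 samples, got {n}")
        for name in _AXIS_COLUMNS:
            arr = getattr(self, name)
            if arr.size != n:
                raise DataError(f"length mismatch: t has {n} samples, {name} has {arr.size}")
        steps = np.diff(self.t)
        if np.any(steps <= 0):
            idx = int(np.argmax(steps <= 0))
            raise DataError(f"time not strictly increasing at index {idx + 1}")
        worst = float(np.max(np.abs(steps - 1.0 / self.fs)))
        if worst >= self.time_tol:
            raise DataError(
                f"sample clock deviates from 1/fs grid by {worst:.3g} s "
                f"(tolerance {self.time_tol:g} s)"
            )

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Span from first to last sample, in seconds."""
        return float(self.t[-1] - self.t[0])


@dataclass(eq=False)
class EventSeries:
    """Beat timestamps in seconds (the t-vector), strictly increasing."""

    times: np.ndarray
    source: str = "pen"

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if self.times.size and float(self.times[0]) < 0:
            raise DataError(f"negative event time {self.times[0]} at index 0")
        if self.times.size >= 2:
            diffs = np.diff(self.times)
            if np.any(diffs <= 0):
                idx = int(np.argmax(diffs <= 0))
                raise DataError(f"event times not strictly increasing at index {idx + 1}")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> float:
        """Seconds from first to last event (0 for fewer than 2 events)."""
        if len(self) < 2:
            return 0.0
        return float(self.times[-1] - self.times[0])


def read_pen_recording(
    path,
    scale: ScaleConfig | None = None,
    *,
    fs: float = 100.0,
    sep: str = ",",
    time_col: str = "t",
    time_tol: float = 1e-3,
) -> AccelRecording:
    """Read a delimited-text pen recording of raw counts into g units.

    ``fs`` is used both to reconstruct the time base when ``time_col``
    is absent and as the recording's nominal rate.
    """
    scale = scale or ScaleConfig()
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty recording file: {path}") from exc
    missing = [c for c in _AXIS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"recording file {path} is missing column(s): {', '.join(missing)}")
    if time_col in df.columns:
        t = df[time_col].to_numpy(dtype=float)
        steps = np.diff(t)
        if t.size >= 2 and np.any(steps <= 0):
            idx = int(np.argmax(steps <= 0))
            raise DataError(f"time column not strictly increasing at index {idx + 1} of {path}")
    else:
        t = np.arange(len(df)) / fs
    meta = {
        "path": str(path),
        "counts_per_g": scale.counts_per_g,
        "full_scale_g": scale.full_scale,
    }
    return AccelRecording(
        t=t,
        ax=scale.to_g(df["ax"].to_numpy()),
        ay=scale.to_g(df["ay"].to_numpy()),
        az=scale.to_g(df["az"].to_numpy()),
        fs=fs,
        meta=meta,
        time_tol=time_tol,
    )


def write_pen_recording(
    rec: AccelRecording,
    path,
    scale: ScaleConfig | None = None,
    *,
    sep: str = ",",
    include_time: bool = True,
) -> None:
    """Write a recording as raw counts; inverse of :func:`read_pen_recording`."""
    scale = scale or ScaleConfig()
    cols = {}
    if include_time:
        cols["t"] = rec.t
    for name in _AXIS_COLUMNS:
        cols[name] = scale.to_counts(getattr(rec, name))
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def read_event_log(
    path,
    *,
    dialect: str = "timestamps",
    origin: float = 0.0,
    sep: str = ",",
    source: str = "ecg",
) -> EventSeries:
    """Read a beat-event log.

    ``dialect="timestamps"`` interprets the single column as beat times
    in seconds; ``dialect="rr"`` interprets it as successive RR intervals
    and reconstructs the times by cumulative summation from ``origin``.
    """
    if dialect not in ("timestamps", "rr"):
        raise ParameterError(f"unknown event-log dialect {dialect!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty event log: {path}") from exc
    if df.shape[0] == 0:
        raise DataError(f"empty event log: {path}")
    values = df.iloc[:, 0].to_numpy(dtype=float)
    if dialect == "rr":
        if np.any(values <= 0):
            idx = int(np.argmax(values <= 0))
            raise DataError(f"non-positive RR interval {values[idx]} at row {idx} of {path}")
        times = origin + np.cumsum(values)
    else:
        times = values
    return EventSeries(times=times, source=source)


def write_event_log(events: EventSeries, path, *, sep: str = ",") -> None:
    pd.DataFrame({"time": events.times}).to_csv(path, sep=sep, index=False)


def write_interval_log(dt: np.ndarray, path, *, sep: str = ",") -> None:
    pd.DataFrame({"dt": np.asarray(dt, dtype=float)}).to_csv(path, sep=sep, index=False)


_REPORT_FORMAT = "penpulse-agreement-report"


def write_report(report, path) -> None:
    """Serialize an AgreementReport to JSON, losslessly and deterministically.

    Floats are written with ``repr`` round-trip precision, so re-reading
    reproduces every field bit-exactly and repeated writes of the same
    report are byte-identical.
    """
    payload = {"format": _REPORT_FORMAT, "version": 1, "report": report.to_dict()}
    text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
    Path(path).write_text(text)


def read_report(path):
    from .agreement import AgreementReport  # deferred to avoid an import cycle

    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _REPORT_FORMAT:
        raise FormatError(f"{path} is not a {_REPORT_FORMAT} file")
    return AgreementReport.from_dict(payload["report"])
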