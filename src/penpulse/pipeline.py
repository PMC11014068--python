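"""End-to-end analysis of one recording: magnitude → detrend → low-pass → beats."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .events import HRSummary, IntervalSeries, PeakParams, detect_peaks, intervals, summarize
from .filtering import apply_filter, design_butterworth
from .io import AccelRecording, EventSeries
from .preprocess import MagnitudeTrace, detrend, magnitude

#: Shortest recording the pipeline accepts, seconds.
MIN_DURATION = 10.0


@dataclass(eq=False)
class AnalysisResult:
    events: EventSeries
    interval_series: IntervalSeries
    summary: HRSummary
    trace: MagnitudeTrace  # filtered trace the peaks were detected on


def analyze_recording(
    rec: AccelRecording,
    *,
    detrend_method: str | None = "mean",
    detrend_window: float | None = None,
    filter_order: int = 4,
    cutoff_hz: float = 2.0,
    zero_phase: bool = True,
    peak_params: PeakParams | None = None,
    min_duration: float = MIN_DURATION,
) -> AnalysisResult:
    """Run the full single-recording pipeline.

    Stages: Euclidean magnitude, optional detrend (``detrend_method=None``
    skips it), Butterworth low-pass (zero-phase by default), beat-peak
    detection, Δt-vector and heart-rate summary.
    """
    if rec.duration < min_duration:
        raise DataError(
            f"recording spans {rec.duration:.2f} s; at least {min_duration:.0f} s required"
        )
    trace = magnitude(rec)
    if detrend_method is not None:
        trace = detrend(trace, method=detrend_method, window=detrend_window)
    spec = design_butterworth(
        order=filter_order, cutoff_hz=cutoff_hz, fs=rec.fs, zero_phase=zero_phase
    )
    filtered = apply_filter(trace, spec)
    events = detect_peaks(filtered, peak_params)
    if len(events) < 2:
        raise DataError(f"only {len(events)} beat(s) detected; cannot form intervals")
    iv = intervals(events)
    return AnalysisResult(events=events, interval_series=iv, summary=summarize(iv), trace=filtered)
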