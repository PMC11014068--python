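"""ECG-anchored calibration of the low-pass cutoff frequency.

The separating cutoff is validated by a scan: for each candidate cutoff
the magnitude trace is filtered, beats are detected, and the detected
beat count is compared with the count from a simultaneously recorded
reference (ECG) beat series.  The selected cutoff minimizes the
absolute count mismatch; ties are broken by the higher Pearson
correlation of matched timestamps, then by the lower cutoff (stronger
noise rejection).  At the selected cutoff an OLS regression of matched
pen timestamps on reference timestamps quantifies residual timing error
— a perfectly aligned pair gives y = x.

This is a development/validation tool: it needs a reference beat
series, which a deployed pen obviously does not have.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .agreement import match_events, pearson
from .errors import DataError, ParameterError
from .events import PeakParams, detect_peaks
from .filtering import apply_filter, design_butterworth
from .io import EventSeries
from .preprocess import MagnitudeTrace


@dataclass(eq=False)
class CutoffScanResult:
    """Outcome of a cutoff-frequency scan against a reference beat series."""

    grid: np.ndarray
    peak_counts: np.ndarray
    objective: np.ndarray
    pearson_r: np.ndarray
    selected_cutoff: float
    regression: tuple[float, float]
    n_reference: int

    def to_dict(self) -> dict:
        return {
            "grid_hz": self.grid.tolist(),
            "peak_counts": self.peak_counts.tolist(),
            "objective": self.objective.tolist(),
            "pearson_r": [None if np.isnan(r) else float(r) for r in self.pearson_r],
            "selected_cutoff_hz": self.selected_cutoff,
            "regression": {"slope": self.regression[0], "intercept": self.regression[1]},
            "n_reference": self.n_reference,
        }


def timestamp_regression(matched_pen, matched_ecg) -> tuple[float, float]:
    """OLS of pen timestamps on reference timestamps: pen = slope·ecg + intercept."""
    pen = np.asarray(matched_pen, dtype=float)
    ecg = np.asarray(matched_ecg, dtype=float)
    if pen.size != ecg.size:
        raise ParameterError(f"length mismatch: {pen.size} vs {ecg.size}")
    if pen.size < 2:
        raise DataError("regression requires at least 2 matched timestamps")
    if np.std(ecg) == 0:
        raise DataError("regression undefined: zero variance in reference timestamps")
    res = stats.linregress(ecg, pen)
    return float(res.slope), float(res.intercept)


def scan_cutoffs(
    trace: MagnitudeTrace,
    reference: EventSeries,
    grid,
    params: PeakParams | None = None,
    *,
    order: int = 4,
    zero_phase: bool = True,
    max_offset: float = 1.0,
) -> CutoffScanResult:
    """Scan candidate low-pass cutoffs against a reference beat series.

    ``trace`` must be unfiltered (raw magnitude or detrended); each
    candidate cutoff is designed and applied afresh.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ParameterError("cutoff grid is empty")
    if np.any(grid <= 0) or np.any(grid >= trace.fs / 2):
        bad = grid[(grid <= 0) | (grid >= trace.fs / 2)][0]
        raise ParameterError(f"cutoff {bad} Hz outside (0, {trace.fs / 2}) Hz")
    if trace.stage == "filtered":
        raise ParameterError("scan_cutoffs expects an unfiltered trace")
    if len(reference) == 0:
        raise DataError("reference event series is empty")
    params = params or PeakParams()

    counts = np.zeros(grid.size, dtype=int)
    objective = np.zeros(grid.size, dtype=int)
    r_values = np.full(grid.size, np.nan)
    matched: list[tuple[np.ndarray, np.ndarray] | None] = []
    for k, cutoff in enumerate(grid):
        spec = design_butterworth(order=order, cutoff_hz=float(cutoff), fs=trace.fs, zero_phase=zero_phase)
        peaks = detect_peaks(apply_filter(trace, spec), params)
        counts[k] = len(peaks)
        objective[k] = abs(len(peaks) - len(reference))
        if len(peaks) >= 2:
            m = match_events(peaks, reference, max_offset=max_offset)
            if m.n_pairs >= 2:
                pen_t = peaks.times[m.pairs[:, 0]]
                ecg_t = reference.times[m.pairs[:, 1]]
                matched.append((pen_t, ecg_t))
                try:
                    r_values[k] = pearson(pen_t, ecg_t)
                except DataError:
                    pass
                continue
        matched.append(None)

    # lexicographic: count mismatch, then correlation (higher better), then lower cutoff
    def key(k: int):
        r = r_values[k]
        return (objective[k], -(-1.0 if np.isnan(r) else r), grid[k])

    best = min(range(grid.size), key=key)
    if matched[best] is None:
        raise DataError(
            f"no matched timestamps at the selected cutoff {grid[best]} Hz; "
            "cannot fit the verification regression"
        )
    regression = timestamp_regression(matched[best][0], matched[best][1])
    return CutoffScanResult(
        grid=grid,
        peak_counts=counts,
        objective=objective,
        pearson_r=r_values,
        selected_cutoff=float(grid[best]),
        regression=regression,
        n_reference=len(reference),
    )
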