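"""Pen-vs-ECG beat alignment and the method-agreement statistics battery.

Two beat-event series recorded by independent devices rarely have equal
length: either detector can miss or hallucinate beats.  All t-vector
statistics therefore operate on a monotone one-to-one matching that
pairs each pen beat with at most one reference beat within a maximum
offset, maximizing the number of pairs (ties broken by minimal total
absolute offset).  Interval (Δt) statistics use only intervals whose
two bounding beats were matched consecutively in both series, so a
missed beat never contaminates a paired interval; each device's own
interval summary and boxplot use its full Δt-vector.

The battery per recording pair: mean Δt ± SD and mean HR per device,
Pearson correlation and cosine similarity of matched t-vectors, mean
squared error and Welch's unequal-variance t-test of the paired
Δt-vectors, the absolute mean-HR deviation, an OLS regression of pen
timestamps on reference timestamps, and five-number Δt summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError, ParameterError, PenPulseWarning
from .events import HRSummary, intervals, summarize
from .io import EventSeries


@dataclass(frozen=True)
class FiveNumberSummary:
    """min, lower quartile, median, upper quartile, max."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    @classmethod
    def from_data(cls, x) -> "FiveNumberSummary":
        x = np.asarray(x, dtype=float)
        if x.size == 0:
            raise DataError("cannot summarize an empty vector")
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return cls(float(np.min(x)), float(q1), float(med), float(q3), float(np.max(x)))

    def to_dict(self) -> dict:
        return {
            "min": self.minimum,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "max": self.maximum,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FiveNumberSummary":
        return cls(d["min"], d["q1"], d["median"], d["q3"], d["max"])


@dataclass(eq=False)
class MatchResult:
    """Monotone one-to-one pairing between two beat series.

    ``pairs`` holds (pen index, reference index) rows, strictly
    increasing in both coordinates; ``offsets`` are
    ``pen − global_shift − reference`` per pair, all within the matcher's
    maximum offset.
    """

    pairs: np.ndarray
    offsets: np.ndarray
    n_unmatched_pen: int
    n_unmatched_ecg: int
    global_shift: float = 0.0

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])


def match_events(
    pen: EventSeries,
    ecg: EventSeries,
    max_offset: float = 1.0,
    *,
    estimate_shift: bool = False,
    shift_grid=None,
) -> MatchResult:
    """Optimally align two beat series.

    The pairing is the monotone one-to-one matching that maximizes the
    number of matched beats subject to ``|pen_i − shift − ecg_j| ≤
    max_offset``, breaking ties by minimal total absolute offset
    (dynamic program, exact).  With ``estimate_shift`` a single global
    clock shift is chosen first by maximizing the pair count over a
    grid (default ±5 s in steps of ``max_offset/4``), for recordings
    whose devices run unsynchronized clocks.
    """
    if not max_offset > 0:
        raise ParameterError(f"max_offset must be positive, got {max_offset}")
    if len(pen) == 0 or len(ecg) == 0:
        raise DataError("both event series must be non-empty")
    pen_t = pen.times
    ecg_t = ecg.times

    shift = 0.0
    if estimate_shift:
        if shift_grid is None:
            step = max_offset / 4.0
            shift_grid = np.arange(-5.0, 5.0 + step / 2, step)
        best = None
        for s in np.asarray(shift_grid, dtype=float):
            score = _match_dp(pen_t - s, ecg_t, max_offset, score_only=True)
            key = (score, -abs(s))  # prefer the smaller shift on ties
            if best is None or key > best[0]:
                best = (key, float(s))
        shift = best[1]

    pairs = _match_dp(pen_t - shift, ecg_t, max_offset, score_only=False)
    if pairs.shape[0] == 0:
        warnings.warn(
            f"no events matched within {max_offset} s (shift {shift:+.3f} s)",
            PenPulseWarning,
            stacklevel=2,
        )
    offsets = pen_t[pairs[:, 0]] - shift - ecg_t[pairs[:, 1]] if pairs.size else np.empty(0)
    return MatchResult(
        pairs=pairs,
        offsets=offsets,
        n_unmatched_pen=len(pen) - pairs.shape[0],
        n_unmatched_ecg=len(ecg) - pairs.shape[0],
        global_shift=shift,
    )


def _match_dp(pen_t, ecg_t, max_offset, *, score_only=False):
    """Exact DP for the max-cardinality, min-cost monotone matching.

    Each cell's value encodes (pairs, −total cost) in one float as
    ``pairs·BIG − cost`` with BIG larger than any achievable cost, so a
    single running maximum implements the lexicographic objective.
    """
    n, m = pen_t.size, ecg_t.size
    big = max_offset * (min(n, m) + 1) + 1.0
    # bonus[i, j] = BIG − |pen_i − ecg_j| where admissible, else −inf
    diff = np.abs(pen_t[:, None] - ecg_t[None, :])
    bonus = np.where(diff <= max_offset, big - diff, -np.inf)

    S = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        cand = np.maximum(S[i - 1, 1:], S[i - 1, :-1] + bonus[i - 1])
        S[i] = np.maximum.accumulate(np.concatenate(([0.0], cand)))
    if score_only:
        return float(S[n, m])

    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        if S[i, j] == S[i - 1, j]:
            i -= 1
        elif S[i, j] == S[i, j - 1]:
            j -= 1
        else:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
    pairs.reverse()
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise DataError("pearson requires at least 2 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("pearson undefined for a zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def cosine_similarity(x, y) -> float:
    """dot(x, y) / (‖x‖·‖y‖), on the raw (uncentred) vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 1:
        raise DataError("cosine similarity requires at least 1 observation")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise DataError("cosine similarity undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))


def mse(y, yhat) -> float:
    """Mean squared error (1/n)·Σ(yj − ŷj)²."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size != yhat.size:
        raise ParameterError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < 1:
        raise DataError("mse requires at least 1 observation")
    return float(np.mean((y - yhat) ** 2))


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom.
    When both samples are constant: ``(0, nx+ny−2, 1)`` if the means
    agree, else ``(±inf, nx+ny−2, 0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("welch_t_test requires at least 2 observations per sample")
    nx, ny = x.size, y.size
    mx, my = np.mean(x), np.mean(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        df = float(nx + ny - 2)
        if mx == my:
            return 0.0, df, 1.0
        return float(np.sign(mx - my) * np.inf), df, 0.0
    t = float((mx - my) / np.sqrt(se2))
    df = float(se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


@dataclass(eq=False)
class AgreementReport:
    """Full agreement battery for one pen/reference recording pair."""

    hr_summary_pen: HRSummary
    hr_summary_ecg: HRSummary
    pearson_r: float
    cosine_similarity: float
    mse_dt: float
    welch_t: float
    welch_df: float
    welch_p: float
    hr_deviation: float
    regression: tuple[float, float]
    boxplot_pen: FiveNumberSummary
    boxplot_ecg: FiveNumberSummary
    median_diff: float
    n_matched: int = 0
    n_paired_dt: int = 0
    global_shift: float = 0.0
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "hr_summary_pen": self.hr_summary_pen.to_dict(),
            "hr_summary_ecg": self.hr_summary_ecg.to_dict(),
            "pearson_r": self.pearson_r,
            "cosine_similarity": self.cosine_similarity,
            "mse_dt": self.mse_dt,
            "welch_t": self.welch_t,
            "welch_df": self.welch_df,
            "welch_p": self.welch_p,
            "hr_deviation": self.hr_deviation,
            "regression": {"slope": self.regression[0], "intercept": self.regression[1]},
            "boxplot_pen": self.boxplot_pen.to_dict(),
            "boxplot_ecg": self.boxplot_ecg.to_dict(),
            "median_diff": self.median_diff,
            "n_matched": self.n_matched,
            "n_paired_dt": self.n_paired_dt,
            "global_shift": self.global_shift,
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementReport":
        return cls(
            hr_summary_pen=HRSummary.from_dict(d["hr_summary_pen"]),
            hr_summary_ecg=HRSummary.from_dict(d["hr_summary_ecg"]),
            pearson_r=d["pearson_r"],
            cosine_similarity=d["cosine_similarity"],
            mse_dt=d["mse_dt"],
            welch_t=d["welch_t"],
            welch_df=d["welch_df"],
            welch_p=d["welch_p"],
            hr_deviation=d["hr_deviation"],
            regression=(d["regression"]["slope"], d["regression"]["intercept"]),
            boxplot_pen=FiveNumberSummary.from_dict(d["boxplot_pen"]),
            boxplot_ecg=FiveNumberSummary.from_dict(d["boxplot_ecg"]),
            median_diff=d["median_diff"],
            n_matched=d.get("n_matched", 0),
            n_paired_dt=d.get("n_paired_dt", 0),
            global_shift=d.get("global_shift", 0.0),
            meta=d.get("meta", {}),
        )


def paired_interval_vectors(
    pen: EventSeries, ecg: EventSeries, match: MatchResult
) -> tuple[np.ndarray, np.ndarray]:
    """Δt vectors restricted to consecutively matched beats.

    An interval enters only when pairs k and k+1 advance by exactly one
    beat in *both* series, i.e. the interval is bounded by the same two
    physiological beats on each device.
    """
    if match.n_pairs < 2:
        return np.empty(0), np.empty(0)
    p = match.pairs
    consecutive = (np.diff(p[:, 0]) == 1) & (np.diff(p[:, 1]) == 1)
    pen_dt = np.diff(pen.times[p[:, 0]])[consecutive]
    ecg_dt = np.diff(ecg.times[p[:, 1]])[consecutive]
    return pen_dt, ecg_dt


def compare(
    pen_events: EventSeries,
    ecg_events: EventSeries,
    max_offset: float = 1.0,
    *,
    estimate_shift: bool = False,
    min_matches: int = 10,
    min_span: float = 60.0,
) -> AgreementReport:
    """Compute the full agreement battery for a pen/reference pair."""
    for series, label in ((pen_events, "pen"), (ecg_events, "reference")):
        if series.span < min_span:
            raise DataError(
                f"{label} series spans {series.span:.1f} s; at least {min_span:.0f} s required"
            )
    match = match_events(
        pen_events, ecg_events, max_offset=max_offset, estimate_shift=estimate_shift
    )
    if match.n_pairs < min_matches:
        raise DataError(
            f"only {match.n_pairs} matched beats (< {min_matches}); series may be misaligned"
        )
    pen_t = pen_events.times[match.pairs[:, 0]]
    ecg_t = ecg_events.times[match.pairs[:, 1]]

    pen_dt_all = intervals(pen_events)
    ecg_dt_all = intervals(ecg_events)
    summary_pen = summarize(pen_dt_all)
    summary_ecg = summarize(ecg_dt_all)

    pen_dt_paired, ecg_dt_paired = paired_interval_vectors(pen_events, ecg_events, match)
    if pen_dt_paired.size < 2:
        raise DataError("fewer than 2 consecutively matched intervals; cannot compare Δt vectors")

    slope, intercept = _ols(ecg_t, pen_t)
    welch_t, welch_df, welch_p = welch_t_test(pen_dt_paired, ecg_dt_paired)
    return AgreementReport(
        hr_summary_pen=summary_pen,
        hr_summary_ecg=summary_ecg,
        pearson_r=pearson(pen_t, ecg_t),
        cosine_similarity=cosine_similarity(pen_t, ecg_t),
        mse_dt=mse(ecg_dt_paired, pen_dt_paired),
        welch_t=welch_t,
        welch_df=welch_df,
        welch_p=welch_p,
        hr_deviation=abs(summary_pen.mean_hr - summary_ecg.mean_hr),
        regression=(slope, intercept),
        boxplot_pen=FiveNumberSummary.from_data(pen_dt_all.dt),
        boxplot_ecg=FiveNumberSummary.from_data(ecg_dt_all.dt),
        median_diff=float(np.median(pen_dt_all.dt) - np.median(ecg_dt_all.dt)),
        n_matched=match.n_pairs,
        n_paired_dt=int(pen_dt_paired.size),
        global_shift=match.global_shift,
        meta={"pen_source": pen_events.source, "ecg_source": ecg_events.source},
    )


def _ols(x, y) -> tuple[float, float]:
    if np.std(x) == 0:
        raise DataError("regression undefined: zero variance in x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)
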