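import numpy as np
import pytest
from scipy import stats

from oracles import optimal_monotone_matching, permutation_welch_p
from penpulse import (
    DataError,
    EventSeries,
    compare,
    cosine_similarity,
    generate_rr_series,
    match_events,
    mse,
    pearson,
    welch_t_test,
)
from penpulse.agreement import paired_interval_vectors


def _series(times, source="pen"):
    return EventSeries(times=np.asarray(times, dtype=float), source=source)


class TestMatchEvents:
    def test_identical_series_fully_paired(self):
        times = np.cumsum(np.full(20, 0.8))
        m = match_events(_series(times), _series(times, "ecg"), max_offset=1.0)
        assert m.n_pairs == 20
        assert m.n_unmatched_pen == m.n_unmatched_ecg == 0
        np.testing.assert_allclose(m.offsets, 0.0)

    def test_constant_delay_all_paired(self):
        ecg = np.cumsum(np.full(30, 0.9))
        m = match_events(_series(ecg + 0.3), _series(ecg, "ecg"), max_offset=1.0)
        assert m.n_pairs == 30
        np.testing.assert_allclose(m.offsets, 0.3)

    def test_pairs_monotone_and_within_offset(self, rng):
        ecg = np.cumsum(rng.uniform(0.6, 1.2, 60))
        pen = ecg[rng.random(60) > 0.05] + rng.uniform(-0.1, 0.1, None)
        m = match_events(_series(np.sort(pen)), _series(ecg, "ecg"), max_offset=0.4)
        assert np.all(np.diff(m.pairs[:, 0]) > 0) and np.all(np.diff(m.pairs[:, 1]) > 0)
        assert np.all(np.abs(m.offsets) <= 0.4)

    @pytest.mark.parametrize("seed", range(40))
    def test_equals_dp_oracle_on_small_series(self, seed):
        """Pair count and total offset match exhaustive optimal monotone
        matching on series of up to 50 events with deletions and jitter."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        ecg = np.cumsum(rng.uniform(0.5, 1.3, n))
        keep = rng.random(n) > rng.uniform(0.0, 0.3)
        if not keep.any():
            keep[0] = True
        pen = np.sort(ecg[keep] + rng.uniform(-0.3, 0.3, keep.sum()))
        max_offset = float(rng.uniform(0.2, 1.0))
        m = match_events(_series(pen), _series(ecg, "ecg"), max_offset=max_offset)
        count, cost = optimal_monotone_matching(pen, ecg, max_offset)
        assert m.n_pairs == count
        assert np.sum(np.abs(m.offsets)) == pytest.approx(cost, abs=1e-9)

    def test_global_shift_estimation_recovers_clock_offset(self):
        ecg = np.cumsum(np.full(50, 0.85))
        pen = ecg + 2.0
        m = match_events(_series(pen), _series(ecg, "ecg"), max_offset=0.3, estimate_shift=True)
        assert m.n_pairs == 50
        assert m.global_shift == pytest.approx(2.0, abs=0.3 / 4)
        assert np.max(np.abs(m.offsets)) <= 0.3

    def test_disjoint_series_warns_and_returns_empty(self):
        with pytest.warns(match="no events matched"):
            m = match_events(_series([1.0, 2.0]), _series([50.0, 51.0], "ecg"), max_offset=1.0)
        assert m.n_pairs == 0

    def test_empty_series_rejected(self):
        with pytest.raises(DataError):
            match_events(_series([]), _series([1.0], "ecg"))


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_formula(self):
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9819805, abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCosine:
    def test_parallel_and_orthogonal(self):
        assert cosine_similarity([1.0, 2.0], [2.0, 4.0]) == pytest.approx(1.0)
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_45_degrees(self):
        assert cosine_similarity([1.0, 0.0], [1.0, 1.0]) == pytest.approx(np.sqrt(0.5))

    def test_zero_vector_rejected(self):
        with pytest.raises(DataError, match="zero"):
            cosine_similarity([0.0, 0.0], [1.0, 1.0])


class TestMse:
    def test_identical_is_zero(self, rng):
        x = rng.random(50)
        assert mse(x, x) == 0.0

    def test_half(self):
        assert mse([1.0, 2.0], [1.0, 3.0]) == pytest.approx(0.5)

    def test_matches_loop_oracle_and_symmetry(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 40))
            y, yhat = rng.standard_normal(n), rng.standard_normal(n)
            loop = sum((a - b) ** 2 for a, b in zip(y, yhat)) / n
            assert mse(y, yhat) == pytest.approx(loop, rel=1e-12)
            assert mse(y, yhat) == pytest.approx(mse(yhat, y), rel=1e-12)


class TestWelch:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        t, df, p = welch_t_test(x, x)
        assert t == 0.0 and p == 1.0

    def test_large_shift_significant(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [11.0, 12.0, 13.0, 14.0]
        _, _, p = welch_t_test(x, y)
        assert p < 0.001

    def test_matches_scipy_cross_check(self, rng):
        """Hand-computed Welch statistic, df and p agree with the independent
        scipy implementation on random unequal-variance samples."""
        for _ in range(25):
            x = rng.normal(0, 1, int(rng.integers(5, 60)))
            y = rng.normal(0.3, 2.5, int(rng.integers(5, 60)))
            t, df, p = welch_t_test(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_convention(self):
        t, _, p = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        t, _, p = welch_t_test([2.0, 2.0], [3.0, 3.0])
        assert np.isinf(t) and p == 0.0

    def test_p_within_permutation_oracle(self):
        """Welch p agrees with a 10⁵-draw permutation test within ±0.02 at
        n = 30 per group."""
        rng = np.random.default_rng(77)
        x = rng.normal(0.0, 1.0, 30)
        y = rng.normal(0.6, 2.0, 30)
        _, _, p = welch_t_test(x, y)
        p_perm = permutation_welch_p(x, y, 100_000, np.random.default_rng(78))
        assert abs(p - p_perm) <= 0.02

    def test_type_i_error_calibration(self):
        """Under the null (both Δt samples from one distribution) the 5% test
        rejects in 5% ± 2% of 1000 replicates."""
        rng = np.random.default_rng(5)
        n = 250
        rejections = 0
        x = rng.normal(0.9, 0.05, (1000, n))
        y = rng.normal(0.9, 0.05, (1000, n))
        mx, my = x.mean(axis=1), y.mean(axis=1)
        vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
        se2 = vx / n + vy / n
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / ((vx / n) ** 2 / (n - 1) + (vy / n) ** 2 / (n - 1))
        p = 2 * stats.t.sf(np.abs(t), df)
        rejections = int(np.sum(p < 0.05))
        assert 30 <= rejections <= 70


class TestCompare:
    def _truth(self, seed=3, duration=300.0):
        return generate_rr_series(72.0, 0.05, duration, seed=seed)

    def test_identical_series_perfect_agreement(self):
        truth = self._truth()
        pen = EventSeries(times=truth.times.copy(), source="pen")
        report = compare(pen, truth, max_offset=1.0)
        assert report.pearson_r == pytest.approx(1.0)
        assert report.cosine_similarity == pytest.approx(1.0)
        assert report.mse_dt == 0.0
        assert report.hr_deviation == 0.0
        assert report.welch_p == 1.0
        assert report.regression[0] == pytest.approx(1.0, abs=1e-12)
        assert report.regression[1] == pytest.approx(0.0, abs=1e-9)
        assert report.median_diff == 0.0

    def test_small_jitter_high_agreement(self):
        """±50 ms uniform jitter keeps Pearson > 0.999 and Welch p > 0.05 in
        at least 95 of 100 seeded replicates."""
        ok = 0
        for seed in range(100):
            truth = generate_rr_series(70.0, 0.05, 300.0, seed=200 + seed)
            jitter = np.random.default_rng(500 + seed).uniform(-0.05, 0.05, len(truth))
            pen = EventSeries(times=truth.times + jitter, source="pen")
            report = compare(pen, truth, max_offset=1.0)
            ok += report.pearson_r > 0.999 and report.welch_p > 0.05
        assert ok >= 95

    def test_truncation_order_invariance(self):
        """Pearson/cosine computed on matched pairs equal the same statistics
        computed on the pair lists extracted independently."""
        truth = self._truth(seed=9)
        keep = np.random.default_rng(9).random(len(truth)) > 0.05
        pen = EventSeries(times=truth.times[keep] + 0.02, source="pen")
        report = compare(pen, truth, max_offset=1.0)
        m = match_events(pen, truth, max_offset=1.0)
        x = pen.times[m.pairs[:, 0]]
        y = truth.times[m.pairs[:, 1]]
        assert report.pearson_r == pytest.approx(pearson(x, y), rel=1e-12)
        assert report.cosine_similarity == pytest.approx(cosine_similarity(x, y), rel=1e-12)

    def test_paired_intervals_skip_dropped_beats(self):
        """An interval bounded by a missed beat never enters the paired Δt."""
        truth = self._truth(seed=4)
        drop = 20
        pen_times = np.delete(truth.times, drop)
        pen = EventSeries(times=pen_times, source="pen")
        m = match_events(pen, truth, max_offset=1.0)
        pen_dt, ecg_dt = paired_interval_vectors(pen, truth, m)
        assert pen_dt.size == len(truth) - 3  # two intervals around the gap lost
        np.testing.assert_allclose(pen_dt, ecg_dt)

    def test_report_has_all_battery_columns(self):
        truth = self._truth(seed=5)
        pen = EventSeries(times=truth.times + 0.01, source="pen")
        d = compare(pen, truth).to_dict()
        expected = {
            "hr_summary_pen",
            "hr_summary_ecg",
            "pearson_r",
            "cosine_similarity",
            "mse_dt",
            "welch_t",
            "welch_df",
            "welch_p",
            "hr_deviation",
            "regression",
            "boxplot_pen",
            "boxplot_ecg",
            "median_diff",
        }
        assert expected <= set(d)
        for key in ("boxplot_pen", "boxplot_ecg"):
            assert set(d[key]) == {"min", "q1", "median", "q3", "max"}

    def test_short_series_rejected(self):
        short = EventSeries(times=np.cumsum(np.full(10, 0.8)))
        with pytest.raises(DataError, match="60"):
            compare(short, short)

    def test_too_few_matches_rejected(self):
        a = EventSeries(times=np.cumsum(np.full(100, 0.8)), source="pen")
        b = EventSeries(times=np.cumsum(np.full(100, 0.8)) + 300.0, source="ecg")
        with pytest.raises(DataError, match="match"):
            with pytest.warns(match="no events matched"):
                compare(a, b)
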