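import numpy as np
import pandas as pd
import pytest

from wearcontext.sleep import (
    COLE_GAIN,
    COLE_WEIGHTS,
    ActivityIndexSeries,
    SleepEstimate,
    activity_index,
    best_two_changepoints,
    compare_sleep,
    detect_sleep_period,
    sleep_wake_scores,
    smooth_and_scale,
)
from wearcontext.synthetic import CohortSpec, NightReport
from wearcontext.timeseries import Channel, Recording

from conftest import make_recording


def _accel_recording(x, y, z, start="2022-03-10 13:00"):
    t0 = pd.Timestamp(start)
    chans = {n: Channel(n, 32.0, t0, v)
             for n, v in (("accel_x", x), ("accel_y", y), ("accel_z", z))}
    return Recording("S0", chans)


@pytest.fixture(scope="module")
def planted_night():
    """One rendered 13:00→13:00 window with rest planted 23:00–07:00."""
    from wearcontext.pipeline import planted_night_recording

    spec = CohortSpec(seed=5)
    return planted_night_recording(spec, seed=404)


class TestActivityIndex:
    def test_constant_axes_give_zero(self):
        n = 32 * 60 * 12
        rec = _accel_recording(np.full(n, 0.3), np.full(n, -0.2), np.full(n, 0.9))
        ai = activity_index(rec)
        assert np.allclose(ai.raw, 0.0)

    def test_iid_noise_recovers_sigma(self):
        rng = np.random.default_rng(0)
        n = 32 * 60 * 12
        sigma = 0.17
        rec = _accel_recording(*[rng.normal(0, sigma, n) for _ in range(3)])
        ai = activity_index(rec)
        np.testing.assert_allclose(ai.raw, sigma, rtol=0.05)

    def test_matches_brute_force_on_hand_built_window(self):
        rng = np.random.default_rng(1)
        n = 32 * 60 * 11
        axes = [rng.normal(0, 0.1, n) + np.linspace(0, s, n)
                for s in (0.5, -0.3, 0.2)]
        ai = activity_index(_accel_recording(*axes))
        # brute force: per-epoch trailing 10 min window, sample-by-sample
        for k, end_min in enumerate(range(10, 12)):
            seg = slice((end_min - 10) * 60 * 32, end_min * 60 * 32)
            expected = np.sqrt(np.mean([np.var(a[seg]) for a in axes]))
            assert ai.raw[k] == pytest.approx(expected, rel=1e-9)

    def test_missing_samples_mark_epoch(self):
        rng = np.random.default_rng(2)
        n = 32 * 60 * 12
        axes = [rng.normal(0, 0.1, n) for _ in range(3)]
        axes[0][32 * 60 * 10 + 5] = np.nan
        ai = activity_index(_accel_recording(*axes))
        assert np.isnan(ai.raw[-1]) and np.isfinite(ai.raw[0])


class TestSmoothAndScale:
    def test_constant_series_scales_to_zero(self):
        s = ActivityIndexSeries(pd.date_range("2022-03-10", periods=50, freq="min"),
                                np.full(50, 0.4))
        out = smooth_and_scale(s)
        assert np.allclose(out.scaled, 0.0)

    def test_bounds_attained(self):
        rng = np.random.default_rng(3)
        s = ActivityIndexSeries(pd.date_range("2022-03-10", periods=200, freq="min"),
                                np.abs(rng.normal(0.1, 0.05, 200)))
        out = smooth_and_scale(s)
        assert out.scaled.min() == 0.0 and out.scaled.max() == 1.0

    def test_scaling_is_rank_preserving(self):
        rng = np.random.default_rng(4)
        raw = np.abs(rng.normal(0.1, 0.05, 300))
        s = ActivityIndexSeries(pd.date_range("2022-03-10", periods=300, freq="min"), raw)
        out = smooth_and_scale(s)
        # min-max scaling is affine on the smoothed series: ranks preserved
        sm = smooth_and_scale(ActivityIndexSeries(s.epoch_start, raw)).scaled
        assert (np.argsort(sm) == np.argsort(out.scaled)).all()

    def test_all_missing_errors(self):
        s = ActivityIndexSeries(pd.date_range("2022-03-10", periods=30, freq="min"),
                                np.full(30, np.nan))
        with pytest.raises(ValueError):
            smooth_and_scale(s)


class TestColeScores:
    def test_zero_activity_scores_sleep(self):
        scores, calls = sleep_wake_scores(np.zeros(100))
        assert np.allclose(scores, 0.0) and calls.all()

    def test_maximal_activity_scores_wake(self):
        # plugging a ≡ 1 into the score formula: gain * sum(w) ≈ 8.07 > 1
        scores, calls = sleep_wake_scores(np.ones(100))
        assert scores[50] == pytest.approx(COLE_GAIN * COLE_WEIGHTS.sum())
        assert not calls[4:-2].any()

    def test_matches_brute_force_weighted_sum(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 1, 40)
        scores, _ = sleep_wake_scores(a)
        for t in (7, 20, 33):
            expected = COLE_GAIN * sum(
                COLE_WEIGHTS[j + 4] * a[t + j] for j in range(-4, 3))
            assert scores[t] == pytest.approx(expected, rel=1e-12)


class TestTwoChangepoints:
    @staticmethod
    def _brute_force(a, min_gap):
        n = len(a)
        best, best_cost = None, np.inf
        for i in range(1, n):
            for j in range(i + min_gap, n):
                cost = sum(len(seg) * np.var(seg)
                           for seg in (a[:i], a[i:j], a[j:]))
                if cost < best_cost:
                    best, best_cost = (i, j), cost
        return best

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(6)
        for trial in range(5):
            a = rng.normal(0, 0.1, 90)
            lo, hi = sorted(rng.choice(np.arange(10, 80), 2, replace=False))
            a[lo:hi] -= rng.uniform(0.3, 1.0)
            got = best_two_changepoints(a, min_gap=10)
            assert got == self._brute_force(a, 10), trial

    def test_full_scale_beats_random_admissible_pairs(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.5, 0.1, 1440)
        a[620:1080] = rng.normal(0.02, 0.01, 460)
        i, j = best_two_changepoints(a, min_gap=300)
        assert 300 <= j - i

        def cost(i_, j_):
            return sum(len(s) * np.var(s) for s in (a[:i_], a[i_:j_], a[j_:]))

        c_opt = cost(i, j)
        for _ in range(500):
            i_ = rng.integers(1, 1440 - 300)
            j_ = rng.integers(i_ + 300, 1440)
            assert c_opt <= cost(i_, j_) + 1e-9

    def test_short_series_returns_none(self):
        assert best_two_changepoints(np.ones(100), min_gap=300) is None


class TestDetection:
    def test_planted_night_recovered(self, planted_night):
        win, onset, offset = planted_night
        est = detect_sleep_period(win)
        assert est.status == "ok"
        assert abs((est.onset - onset).total_seconds()) <= 20 * 60
        assert abs((est.offset - offset).total_seconds()) <= 20 * 60
        assert est.duration_minutes == pytest.approx(
            (est.offset - est.onset).total_seconds() / 60)

    def test_shift_equivariance(self, planted_night):
        win, _, _ = planted_night
        shift = pd.Timedelta(minutes=17)
        shifted = Recording(win.subject_id, {
            n: Channel(n, c.sampling_rate, c.start_time + shift, c.values)
            for n, c in win.channels.items()})
        e0 = detect_sleep_period(win)
        e1 = detect_sleep_period(shifted)
        assert e1.onset - e0.onset == shift
        assert e1.offset - e0.offset == shift

    def test_scale_robustness(self, planted_night):
        win, _, _ = planted_night
        scaled = Recording(win.subject_id, {
            n: Channel(n, c.sampling_rate, c.start_time, c.values * 3.7)
            for n, c in win.channels.items()})
        e0, e1 = detect_sleep_period(win), detect_sleep_period(scaled)
        assert (e0.onset, e0.offset) == (e1.onset, e1.offset)

    def test_uniformly_active_day_yields_no_sleep(self):
        rng = np.random.default_rng(8)
        n = 32 * 86400
        rec = _accel_recording(*[rng.normal(0, 0.15, n) for _ in range(3)])
        est = detect_sleep_period(rec)
        assert est.status == "no_sleep_detected"


class TestCompare:
    def _estimate(self):
        t = pd.Timestamp("2022-03-10 23:00")
        return SleepEstimate(pd.Timestamp("2022-03-10 13:00"), t,
                             t + pd.Timedelta(hours=8))

    def test_equal_times_zero_deltas(self):
        est = self._estimate()
        rep = NightReport("S0", pd.Timestamp("2022-03-11"), est.onset, est.offset)
        d = compare_sleep(est, rep)
        assert d == {"onset_delta": 0.0, "offset_delta": 0.0, "duration_delta": 0.0}

    def test_shifted_report_delta(self):
        est = self._estimate()
        rep = NightReport("S0", pd.Timestamp("2022-03-11"),
                          est.onset + pd.Timedelta(minutes=30), est.offset)
        d = compare_sleep(est, rep)
        assert d["onset_delta"] == 30.0
        assert d["duration_delta"] == -30.0

    def test_no_sleep_excluded(self):
        est = SleepEstimate(pd.Timestamp("2022-03-10 13:00"), None, None,
                            "no_sleep_detected")
        rep = NightReport("S0", pd.Timestamp("2022-03-11"),
                          pd.Timestamp("2022-03-10 23:00"),
                          pd.Timestamp("2022-03-11 07:00"))
        assert compare_sleep(est, rep) is None
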