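import numpy as np
import pandas as pd
import pytest

from wearcontext.synthetic import (
    CohortSpec,
    SelfReportNoise,
    render_reports,
    render_signals,
    sample_profile,
    sample_schedule,
    sample_subject,
    render_subject_recording,
    subject_streams,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestSchedules:
    def test_deterministic_under_fixed_seed(self):
        spec = CohortSpec(n_days=1, seed=5)
        s1 = sample_schedule(spec, "S0", 0, _rng(42))
        s2 = sample_schedule(spec, "S0", 0, _rng(42))
        assert s1 == s2

    def test_invariants_over_many_schedules(self):
        spec = CohortSpec(seed=1)
        rng = _rng(1)
        for day in range(200):
            s = sample_schedule(spec, "S0", day % 5, rng)
            assert 4.0 <= s.sleep_duration_hours <= 11.0
            # bouts tile the waking period without overlap
            assert s.activity_bouts[-1][1] == s.sleep_onset
            for (a0, a1, _), (b0, b1, _) in zip(s.activity_bouts,
                                                s.activity_bouts[1:]):
                assert a1 == b0
                assert a0 < a1
            # stress episodes ordered and non-overlapping
            for (e0, e1, lev) in s.stress_episodes:
                assert e0 < e1 and 2 <= lev <= 5
            for (_, a1, _), (b0, _, _) in zip(s.stress_episodes,
                                              s.stress_episodes[1:]):
                assert b0 >= a1

    def test_short_night_raises_stress_probability(self):
        spec = CohortSpec(seed=2)
        rng = _rng(3)
        n_short = sum(len(sample_schedule(spec, "S", 0, rng,
                                          prev_duration=4.5).stress_episodes)
                      for _ in range(150))
        rng = _rng(3)
        n_long = sum(len(sample_schedule(spec, "S", 0, rng,
                                         prev_duration=9.5).stress_episodes)
                     for _ in range(150))
        assert n_short > 1.3 * n_long


class TestSignals:
    def test_identical_schedule_and_seed_identical_recording(self, fast_spec):
        sched = sample_schedule(fast_spec, "S0", 0, _rng(7))
        prof = sample_profile(fast_spec, _rng(8))
        r1 = render_signals(sched, fast_spec, _rng(9), profile=prof)
        r2 = render_signals(sched, fast_spec, _rng(9), profile=prof)
        for name in r1.channels:
            np.testing.assert_array_equal(r1[name].values, r2[name].values)

    def test_channel_lengths(self, fast_spec):
        sched = sample_schedule(fast_spec, "S0", 0, _rng(7))
        rec = render_signals(sched, fast_spec, _rng(9))
        assert rec["accel_x"].n_samples == 86400 * 32
        assert rec["gsr"].n_samples == 86400 * 4
        assert (rec["gsr"].values >= 0).all()

    def test_walking_variance_exceeds_sedentary(self, fast_spec):
        sched = sample_schedule(fast_spec, "S0", 0, _rng(17))
        rec = render_signals(sched, fast_spec, _rng(18))
        day0 = sched.day_start

        def seg_var(kind):
            vs = []
            for b0, b1, k in sched.activity_bouts:
                if k != kind:
                    continue
                i0 = int((b0 - day0).total_seconds()) * 32
                i1 = int((b1 - day0).total_seconds()) * 32
                vs.append(np.var(rec["accel_x"].values[i0:i1]))
            return np.mean(vs) if vs else None

        v_walk, v_sed = seg_var("walking"), seg_var("sedentary")
        assert v_walk is not None and v_sed is not None
        assert v_walk > v_sed

    def test_multiday_recording_length(self):
        spec = CohortSpec(n_subjects=1, n_days=2, seed=4)
        sid, ss = subject_streams(spec)[0]
        data = sample_subject(spec, sid, ss)
        rec = render_subject_recording(spec, data, ss)
        assert rec["accel_x"].n_samples == 2 * 86400 * 32


class TestReports:
    def _noiseless(self):
        return SelfReportNoise(sleep_report_sd=0.0, activity_omission_prob=0.0,
                               report_missing_prob=0.0, level_flip_prob=0.0)

    def test_noiseless_reports_reproduce_schedule(self, fast_spec):
        from wearcontext.stress import TOKEN_CLASS
        sched = sample_schedule(fast_spec, "S0", 0, _rng(21))
        reports, night = render_reports(sched, self._noiseless(), _rng(22),
                                        amp_slope=0.0)
        assert night.bed_time == sched.sleep_onset
        assert night.getup_time == sched.sleep_offset
        for rep in reports:
            h0, h1 = rep.hour_start, rep.hour_start + pd.Timedelta(hours=1)
            true_classes = {k for b0, b1, k in sched.activity_bouts
                            if b0 < h1 and b1 > h0}
            assert {TOKEN_CLASS[t] for t in rep.activities} == true_classes
            true_level = max([lev for e0, e1, lev in sched.stress_episodes
                              if e0 < h1 and e1 > h0], default=1)
            assert rep.stress_1to5 == true_level

    def test_full_omission_empties_activity_sets(self, fast_spec):
        noise = SelfReportNoise(activity_omission_prob=1.0,
                                report_missing_prob=0.0, level_flip_prob=0.0)
        sched = sample_schedule(fast_spec, "S0", 0, _rng(23))
        reports, _ = render_reports(sched, noise, _rng(24), amp_slope=0.0)
        assert reports and all(len(r.activities) == 0 for r in reports)

    def test_missing_prob_one_drops_everything(self, fast_spec):
        noise = SelfReportNoise(report_missing_prob=1.0)
        sched = sample_schedule(fast_spec, "S0", 0, _rng(25))
        reports, _ = render_reports(sched, noise, _rng(26))
        assert reports == []


class TestCohortStructure:
    def test_subject_sampling_deterministic(self):
        spec = CohortSpec(n_subjects=2, n_days=1, seed=7)
        for (sid1, ss1), (sid2, ss2) in zip(subject_streams(spec),
                                            subject_streams(spec)):
            d1 = sample_subject(spec, sid1, ss1)
            d2 = sample_subject(spec, sid2, ss2)
            assert d1.schedules == d2.schedules
            assert d1.hourly_reports == d2.hourly_reports

    def test_confound_cycling_vs_stressed_sedentary_rates(self):
        """The generator's design rates put unstressed cycling within a
        factor ~2 of a stressed sedentary hour's phasic-response rate."""
        spec = CohortSpec()
        cyc = spec.phasic_rate_awake + spec.phasic_rate_exercise["cycling"]
        stressed = {lev: spec.phasic_rate_awake + add
                    for lev, add in spec.phasic_rate_stress.items()}
        for lev, rate in stressed.items():
            ratio = max(cyc, rate) / min(cyc, rate)
            assert ratio < 2.5, (lev, ratio)

    def test_separability_floor_variance_threshold(self):
        """With far-apart activity noise sds and confounders off, a trivial
        variance threshold classifies 15 s windows at > 95 % accuracy."""
        from wearcontext.synthetic import DaySchedule
        from wearcontext.timeseries import slide_windows
        spec = CohortSpec(
            seed=3,
            accel_noise_sd={"sedentary": 0.01, "walking": 0.1, "cycling": 0.5},
            gait_band_sd=0.0, cadence_band_sd=0.0,
            gesture_rate_per_hour=0.0, p_chore_hour=0.0,
            accel_gain_sigma=0.0,
        )
        day0 = pd.Timestamp(spec.start_date)
        t = day0 + pd.Timedelta(hours=9)
        bouts = []
        for kind in ("sedentary", "walking", "cycling") * 4:
            bouts.append((t, t + pd.Timedelta(minutes=5), kind))
            t += pd.Timedelta(minutes=5)
        sched = DaySchedule(day0, day0 + pd.Timedelta(hours=23),
                            day0 + pd.Timedelta(hours=31), bouts, [])
        rec = render_signals(sched, spec, _rng(31)).slice(bouts[0][0], t)
        wins = slide_windows(rec, 15.0, 0.5)
        labels, variances = [], []
        for w in wins:
            w_end = w.start + pd.Timedelta(seconds=15)
            for b0, b1, kind in bouts:
                if b0 <= w.start and w_end <= b1:
                    labels.append(kind)
                    variances.append(np.var(w.samples["accel_x"]))
                    break
        variances = np.array(variances)
        pred = np.where(variances < 0.01 ** 2 * 9, "sedentary",
                        np.where(variances < 0.1 ** 2 * 9, "walking", "cycling"))
        acc = np.mean(pred == np.array(labels))
        assert acc > 0.95
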