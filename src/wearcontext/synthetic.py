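"""Synthetic multimodal wearable cohorts with known ground truth.

Generates labelled days of wrist-wearable data (3-axis accelerometer at
32 Hz, GSR and skin temperature at 4 Hz) plus hourly self-reports and
nightly sleep reports, with the statistical structure the downstream
analysis assumes:

* activity-dependent accelerometer variance with narrowband gait/cadence
  components (sedentary < walking < cycling noise sd), near-still sleep;
* a galvanic-skin-response model with slow tonic drift and discrete phasic
  responses whose rate rises both under psychological stress and during
  exercise — the stress/exercise confound that motivates context-aware
  stress models;
* skin temperature level shifts with sleep, exercise and stress;
* noisy, incomplete self-reports (activity omissions, missing reports,
  Gaussian error on reported bed/get-up times).

The signal models are deliberately simple parametric processes (Gaussian
noise + band-limited noise + Poisson-like phasic events): controllable and
fast, not physiologically faithful.  Per-subject response gains, wrist
gestures in every waking state, and intermittent "chore" motion (including
sustained exercise look-alikes without the arousal response) make hourly
accelerometer statistics an imperfect proxy for activity, so context
features carry information the physiology alone does not.

Everything is deterministic given a :class:`CohortSpec` (including its
seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import Channel, Recording, write_recording

ACTIVITIES = ("sedentary", "walking", "cycling")

#: app vocabulary tokens per activity class
APP_TOKENS = {
    "sedentary": ("sitting", "standing", "lying_down"),
    "walking": ("walking", "running"),
    "cycling": ("biking",),
}

#: self-reports are prompted between these clock hours (inclusive start,
#: exclusive end), mirroring daytime-only questionnaires
REPORT_HOURS = (7, 22)


@dataclass
class SelfReportNoise:
    """Noise model for the self-reported streams."""

    sleep_report_sd: float = 35.0       # minutes, error on bed/get-up times
    activity_omission_prob: float = 0.1  # per-token drop probability
    report_missing_prob: float = 0.15    # whole hourly report dropped
    level_flip_prob: float = 0.2         # reported stress level off by one

    def __post_init__(self) -> None:
        if not (0 <= self.activity_omission_prob <= 1
                and 0 <= self.report_missing_prob <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.sleep_report_sd < 0:
            raise ValueError("sleep_report_sd must be >= 0")


@dataclass
class CohortSpec:
    """All knobs of the generator; defaults define the study conditions."""

    n_subjects: int = 50
    n_days: int = 5
    seed: int = 0
    start_date: str = "2022-03-10"  # a Thursday, matching a Thu-Mon protocol

    # accelerometer (units of g)
    accel_noise_sd: dict = field(default_factory=lambda: {
        "sedentary": 0.02, "walking": 0.06, "cycling": 0.15})
    sleep_accel_sd: float = 0.005
    gait_freq: float = 1.9          # Hz, walking arm-swing band center
    gait_band_sd: float = 0.09      # narrowband (quasi-periodic) component
    gait_band_halfwidth: float = 0.35
    cadence_freq: float = 1.4       # Hz, cycling (weak: handlebar grip)
    cadence_band_sd: float = 0.05
    accel_gain_sigma: float = 0.35  # per-subject lognormal accel gain
    gesture_rate_per_hour: float = 40.0   # sedentary wrist-gesture bursts
    gesture_sd: float = 0.12
    gesture_secs: float = 2.0
    sleep_move_rate_per_hour: float = 2.0
    sleep_move_sd: float = 0.08
    sleep_move_secs: float = 3.0
    # intermittent non-exercise motion ("chores") inside sedentary hours:
    # bursty broadband segments that blur hour-level accel statistics
    p_chore_hour: float = 0.45
    p_chore_stress_boost: float = 0.25  # restlessness: more fidgeting/chore
    # motion during stressed hours (psychomotor agitation)
    chore_minutes: tuple = (10.0, 30.0)
    chore_on_sd: tuple = (0.08, 0.16)
    chore_on_secs: tuple = (3.0, 10.0)
    chore_off_secs: tuple = (3.0, 10.0)
    chore_phasic_rate: float = 0.5  # light activity barely raises EDA
    chore_band_freq: tuple = (0.6, 3.0)   # rhythmic chores: typing, stirring
    chore_band_sd: tuple = (0.03, 0.10)
    # fraction of chores that are sustained exercise look-alikes in the
    # accelerometer (scrubbing, ironing): same band/variance/duration
    # texture as a walking or cycling bout but without the arousal response
    chore_mimic_prob: float = 0.7

    # GSR (microsiemens)
    gsr_baseline_mean: float = 2.0
    gsr_baseline_sd: float = 0.3
    gsr_drift_amp: float = 0.3
    gsr_gain_sigma: float = 0.4     # per-subject lognormal response gain
    phasic_rate_awake: float = 1.0  # events per minute
    phasic_rate_sleep: float = 0.2
    phasic_rate_stress: dict = field(default_factory=lambda: {
        2: 3.0, 3: 5.0, 4: 7.0, 5: 9.0})
    phasic_rate_exercise: dict = field(default_factory=lambda: {
        "walking": 4.5, "cycling": 6.5})
    phasic_amp_mean: float = 0.4
    phasic_rise: float = 0.75       # seconds
    phasic_decay: float = 3.0
    rate_factor_sigma: float = 0.5  # per-subject lognormal EDA lability
    episode_intensity_jitter: tuple = (0.6, 1.4)

    # skin temperature (deg C)
    temp_base_mean: float = 31.0
    temp_base_sd: float = 0.5
    temp_sleep_delta: float = 1.5
    temp_exercise_delta: dict = field(default_factory=lambda: {
        "walking": 0.6, "cycling": 0.6})
    temp_stress_delta: float = 0.6
    temp_noise_sd: float = 0.05

    # schedule
    wake_mean_hour: float = 7.0
    wake_sd_min: float = 30.0
    bed_mean_hour: float = 23.25
    bed_sd_min: float = 40.0
    sleep_dur_mean: float = 7.5     # hours
    sleep_dur_sd: float = 1.2
    p_walk_hour: float = 0.125
    p_cycle_hour: float = 0.125
    p_stress_base: float = 0.30
    stress_sleep_slope: float = 0.28  # added stress probability per hour of
    # sleep debt below the reference night (graded sleep-stress link)
    sleep_reference_hours: float = 7.5
    p_stress_exercise_hour: float = 0.02
    stress_level_probs: dict = field(default_factory=lambda: {
        2: 0.35, 3: 0.30, 4: 0.20, 5: 0.15})
    stress_minutes: tuple = (20.0, 90.0)  # episode duration range
    level_debt_tilt: float = 0.45  # log-odds tilt of episode level per hour
    # of sleep debt: short nights breed more intense episodes
    appraisal_amp_slope: float = 0.6  # probability per hour of sleep debt
    # that an hour is *reported* one level higher than its physiological
    # intensity (irritable appraisal under sleep deprivation); invisible to
    # the wearable, so sleep context carries information physiology cannot

    noise: SelfReportNoise = field(default_factory=SelfReportNoise)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        sds = self.accel_noise_sd
        if not (sds["sedentary"] < sds["walking"] < sds["cycling"]):
            raise ValueError("accel sds must be ordered sedentary < walking < cycling")


@dataclass
class DaySchedule:
    """Ground truth for one subject-day (00:00–24:00, sleep may cross midnight)."""

    day_start: pd.Timestamp
    sleep_onset: pd.Timestamp      # that evening
    sleep_offset: pd.Timestamp     # next morning
    activity_bouts: list           # [(start, end, activity)] tiling waking time
    stress_episodes: list          # [(start, end, level in 2..5)]
    sleep_debt_hours: float = 0.0  # reference minus previous night's sleep

    @property
    def wake_time(self) -> pd.Timestamp:
        return self.activity_bouts[0][0]

    @property
    def sleep_duration_hours(self) -> float:
        return (self.sleep_offset - self.sleep_onset).total_seconds() / 3600.0


@dataclass
class HourlyReport:
    subject: str
    hour_start: pd.Timestamp
    stress_1to5: int
    activities: frozenset  # app-vocabulary tokens


@dataclass
class NightReport:
    subject: str
    date: pd.Timestamp      # morning date (date of getting up)
    bed_time: pd.Timestamp
    getup_time: pd.Timestamp


@dataclass
class SubjectProfile:
    """Per-subject constants sampled once per cohort subject.

    The accelerometer gain and EDA rate factor encode inter-individual
    variability: under subject-grouped cross-validation they prevent simple
    amplitude thresholds learned on one subject pool from transferring
    cleanly to unseen subjects.
    """

    gravity: np.ndarray          # resting orientation, units of g
    gsr_baseline: float
    gsr_gain: float              # amplitude gain on phasic responses
    rate_factor: float           # multiplicative EDA lability (event rate)
    accel_gain: float            # multiplies all accel noise sds and amps
    temp_base: float


def sample_profile(spec: CohortSpec, rng: np.random.Generator) -> SubjectProfile:
    g = np.array([0.3, -0.2, 0.9]) + rng.normal(0, 0.05, size=3)
    return SubjectProfile(
        gravity=g,
        gsr_baseline=max(0.5, rng.normal(spec.gsr_baseline_mean, spec.gsr_baseline_sd)),
        gsr_gain=float(np.exp(rng.normal(0.0, spec.gsr_gain_sigma))),
        rate_factor=float(np.exp(rng.normal(0.0, spec.rate_factor_sigma))),
        accel_gain=float(np.exp(rng.normal(0.0, spec.accel_gain_sigma))),
        temp_base=rng.normal(spec.temp_base_mean, spec.temp_base_sd),
    )


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def _plan_bouts(
    spec: CohortSpec,
    wake: pd.Timestamp,
    onset: pd.Timestamp,
    rng: np.random.Generator,
) -> tuple[list, dict]:
    """Hour-by-hour bout plan tiling the waking period [wake, onset)."""
    segments: list[tuple[pd.Timestamp, pd.Timestamp, str]] = []
    exercise_hours: dict[pd.Timestamp, str] = {}
    hour = wake.floor("h")
    while hour < onset:
        h0, h1 = max(hour, wake), min(hour + pd.Timedelta(hours=1), onset)
        u = rng.uniform()
        if u < spec.p_walk_hour:
            kind = "walking"
        elif u < spec.p_walk_hour + spec.p_cycle_hour:
            kind = "cycling"
        else:
            kind = "sedentary"
        if kind != "sedentary" and (h1 - h0) >= pd.Timedelta(minutes=20):
            slot_min = (h1 - h0).total_seconds() / 60.0
            dur_min = min(rng.uniform(15, 40), slot_min)
            slack = slot_min - dur_min
            b0 = h0 + pd.Timedelta(minutes=float(rng.uniform(0, max(slack, 0))))
            b1 = b0 + pd.Timedelta(minutes=dur_min)
            segments.extend([(h0, b0, "sedentary"), (b0, b1, kind), (b1, h1, "sedentary")])
            exercise_hours[hour] = kind
        else:
            segments.append((h0, h1, "sedentary"))
        hour += pd.Timedelta(hours=1)
    # merge adjacent sedentary segments, drop empty ones
    bouts: list[tuple[pd.Timestamp, pd.Timestamp, str]] = []
    for s0, s1, kind in segments:
        if s1 <= s0:
            continue
        if bouts and bouts[-1][2] == kind and bouts[-1][1] == s0:
            bouts[-1] = (bouts[-1][0], s1, kind)
        else:
            bouts.append((s0, s1, kind))
    return bouts, exercise_hours


def planted_schedule(
    spec: CohortSpec,
    day_start: pd.Timestamp,
    wake: pd.Timestamp,
    sleep_onset: pd.Timestamp,
    sleep_offset: pd.Timestamp,
    rng: np.random.Generator,
) -> DaySchedule:
    """Schedule with fixed sleep times and sampled bouts, no stress; used to
    plant known rest periods when evaluating the sleep detector."""
    bouts, _ = _plan_bouts(spec, wake, sleep_onset, rng)
    return DaySchedule(pd.Timestamp(day_start).normalize(), sleep_onset,
                       sleep_offset, bouts, [])


def sample_schedule(
    spec: CohortSpec,
    subject: str,
    day: int,
    rng: np.random.Generator,
    prev_offset: pd.Timestamp | None = None,
    prev_duration: float | None = None,
) -> DaySchedule:
    """One day's ground-truth schedule.

    ``prev_offset`` (this morning's wake, i.e. last night's sleep offset)
    chains consecutive days; when absent a morning wake time is sampled.
    Stress-episode probability is elevated after a short previous night,
    encoding the sleep–stress link.
    """
    day_start = pd.Timestamp(spec.start_date).normalize() + pd.Timedelta(days=day)
    if prev_offset is None:
        wake = day_start + pd.Timedelta(
            hours=spec.wake_mean_hour, minutes=float(rng.normal(0, spec.wake_sd_min)))
    else:
        wake = prev_offset
    onset_h = float(np.clip(
        spec.bed_mean_hour + rng.normal(0, spec.bed_sd_min) / 60.0, 21.0, 25.0))
    onset = day_start + pd.Timedelta(hours=onset_h)
    dur = float(np.clip(rng.normal(spec.sleep_dur_mean, spec.sleep_dur_sd), 4.0, 11.0))
    offset = onset + pd.Timedelta(hours=dur)

    bouts, exercise_hours = _plan_bouts(spec, wake, onset, rng)

    # stress episodes: variable-duration bouts (so their temporal footprint
    # resembles exercise bouts), preferentially in non-exercise hours, with
    # probability graded by the previous night's sleep debt
    debt = 0.0 if prev_duration is None else spec.sleep_reference_hours - prev_duration
    p_sed = float(np.clip(spec.p_stress_base + spec.stress_sleep_slope * debt,
                          0.05, 0.80))
    levels = sorted(spec.stress_level_probs)
    probs = np.array([spec.stress_level_probs[k] for k in levels], dtype=float)
    probs /= probs.sum()
    episodes: list[tuple[pd.Timestamp, pd.Timestamp, int]] = []
    hour = wake.ceil("h")
    while hour + pd.Timedelta(hours=1) <= onset:
        p = spec.p_stress_exercise_hour if hour in exercise_hours else p_sed
        if rng.uniform() < p:
            dur_min = rng.uniform(*spec.stress_minutes)
            e0 = hour + pd.Timedelta(minutes=float(rng.uniform(0, 40)))
            e1 = min(e0 + pd.Timedelta(minutes=dur_min), onset)
            if episodes and e0 < episodes[-1][1]:
                e0 = episodes[-1][1]
            if e1 - e0 >= pd.Timedelta(minutes=15):
                tilt = np.exp(spec.level_debt_tilt * debt * np.arange(len(levels)))
                p_lvl = probs * tilt
                level = int(rng.choice(levels, p=p_lvl / p_lvl.sum()))
                episodes.append((e0, e1, level))
        hour += pd.Timedelta(hours=1)

    return DaySchedule(day_start, onset, offset, bouts, episodes,
                       sleep_debt_hours=debt)


def sample_subject_schedules(
    spec: CohortSpec, subject: str, rng: np.random.Generator
) -> list[DaySchedule]:
    """Chained schedules for all days of one subject."""
    scheds: list[DaySchedule] = []
    prev_offset = prev_dur = None
    for day in range(spec.n_days):
        s = sample_schedule(spec, subject, day, rng,
                            prev_offset=prev_offset, prev_duration=prev_dur)
        scheds.append(s)
        prev_offset, prev_dur = s.sleep_offset, s.sleep_duration_hours
    return scheds


# ---------------------------------------------------------------------------
# signal rendering
# ---------------------------------------------------------------------------

_STATE_SLEEP, _STATE_SED, _STATE_WALK, _STATE_CYC = 0, 1, 2, 3
_STATE_OF = {"sedentary": _STATE_SED, "walking": _STATE_WALK, "cycling": _STATE_CYC}
DAY_SECONDS = 86400


def _second_index(ts: pd.Timestamp, day_start: pd.Timestamp) -> int:
    return int((ts - day_start).total_seconds())


def _day_state_arrays(schedule: DaySchedule) -> tuple[np.ndarray, np.ndarray]:
    """(state, stress_level) per second of the day; sleep outside bouts."""
    state = np.full(DAY_SECONDS, _STATE_SLEEP, dtype=np.int8)
    level = np.ones(DAY_SECONDS, dtype=np.int8)
    d0 = schedule.day_start
    for b0, b1, kind in schedule.activity_bouts:
        i0 = np.clip(_second_index(b0, d0), 0, DAY_SECONDS)
        i1 = np.clip(_second_index(b1, d0), 0, DAY_SECONDS)
        state[i0:i1] = _STATE_OF[kind]
    for e0, e1, lev in schedule.stress_episodes:
        i0 = np.clip(_second_index(e0, d0), 0, DAY_SECONDS)
        i1 = np.clip(_second_index(e1, d0), 0, DAY_SECONDS)
        level[i0:i1] = lev
    return state, level


def _band_noise(n: int, fs: float, f0: float, half_bw: float, sd: float,
                rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise: quasi-periodic motion with a Gaussian
    amplitude marginal (unlike a pure tone, whose bimodal marginal would be
    visible to hour-level distribution statistics)."""
    from scipy import signal as _sg
    lo = max(f0 - half_bw, 0.05)
    hi = min(f0 + half_bw, fs / 2 * 0.95)
    white = rng.normal(0.0, 1.0, n)
    if n < 50:
        return white * sd
    sos = _sg.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = _sg.sosfiltfilt(sos, white)
    return y * (sd / max(y.std(), 1e-9))


def _add_bursts(axes: list[np.ndarray], seconds: np.ndarray, rate_per_hour: float,
                sd: float, dur_s: float, rng: np.random.Generator, fs: int = 32) -> None:
    """Short high-variance movement bursts at random seconds (in place)."""
    if len(seconds) == 0 or rate_per_hour <= 0:
        return
    n_bursts = rng.poisson(rate_per_hour * len(seconds) / 3600.0)
    if n_bursts == 0:
        return
    starts = rng.choice(seconds, size=n_bursts)
    w = int(dur_s * fs)
    for s in starts:
        i0 = int(s) * fs
        for ax in axes:
            ax[i0:i0 + w] += rng.normal(0, sd, size=min(w, len(ax) - i0))


def _chore_segments(spec: CohortSpec, state: np.ndarray, level: np.ndarray,
                    rng: np.random.Generator) -> list[tuple[np.ndarray, str]]:
    """Chore segments inside sedentary hours (household motion: not
    exercise, barely arousing, but motion).  Each segment is either choppy
    bursty motion or a sustained exercise look-alike; stressed hours get
    extra chore motion (restlessness)."""
    segments: list[tuple[np.ndarray, str]] = []
    for h0 in range(0, DAY_SECONDS, 3600):
        sed = np.flatnonzero(state[h0:h0 + 3600] == _STATE_SED)
        if len(sed) < 600:
            continue
        p = spec.p_chore_hour
        if (level[h0:h0 + 3600] >= 2).any():
            p += spec.p_chore_stress_boost
        if rng.uniform() >= p:
            continue
        if rng.uniform() < spec.chore_mimic_prob:
            kind = "mimic_walk" if rng.uniform() < 0.5 else "mimic_cycle"
            dur = int(rng.uniform(15, 40) * 60)  # matches exercise bouts
        else:
            kind = "choppy"
            dur = int(rng.uniform(*spec.chore_minutes) * 60)
        start = int(rng.choice(sed))
        seg = np.arange(start, min(start + dur, 3600))
        seg = seg[state[h0 + seg] == _STATE_SED]
        if len(seg):
            segments.append((h0 + seg, kind))
    return segments


def _exercise_texture(axes: list, i0: int, i1: int, kind: str,
                      spec: CohortSpec, profile: SubjectProfile,
                      rng: np.random.Generator, extra_broadband: float = 0.0,
                      fs: int = 32) -> None:
    """Add the walking/cycling accel texture over samples [i0, i1).

    ``extra_broadband`` raises the broadband floor (used by look-alike
    chores, whose underlying state keeps the sedentary noise sd)."""
    if i1 <= i0:
        return
    f0 = spec.gait_freq if kind == "walking" else spec.cadence_freq
    f = f0 + rng.normal(0, 0.1)
    band_sd = profile.accel_gain * (
        spec.gait_band_sd if kind == "walking" else spec.cadence_band_sd)
    for ax in axes:
        ax[i0:i1] += _band_noise(i1 - i0, fs, f, spec.gait_band_halfwidth,
                                 band_sd * rng.uniform(0.8, 1.2), rng)
        if extra_broadband > 0:
            ax[i0:i1] += rng.normal(0, profile.accel_gain * extra_broadband,
                                    size=i1 - i0)


def _render_chores(axes: list, segments: list, spec: CohortSpec,
                   profile: SubjectProfile, rng: np.random.Generator,
                   fs: int = 32) -> None:
    """Chore motion (in place): choppy bursts or exercise look-alikes."""
    n = len(axes[0])
    sed_sd = spec.accel_noise_sd["sedentary"]
    for seconds, kind in segments:
        runs = np.split(seconds, np.flatnonzero(np.diff(seconds) > 1) + 1)
        if kind != "choppy":
            ex = "walking" if kind == "mimic_walk" else "cycling"
            # broadband delta so total variance matches the exercise state
            target = spec.accel_noise_sd[ex]
            extra = float(np.sqrt(max(target ** 2 - sed_sd ** 2, 0.0)))
            for run in runs:
                _exercise_texture(axes, run[0] * fs, (run[-1] + 1) * fs, ex,
                                  spec, profile, rng, extra_broadband=extra)
            continue
        for run in runs:
            t = run[0]
            end = run[-1] + 1
            # choppy chores mix a rhythmic narrowband component (typing,
            # stirring) with broadband bursts at ~50 % duty cycle
            band_f = rng.uniform(*spec.chore_band_freq)
            band_sd = profile.accel_gain * rng.uniform(*spec.chore_band_sd)
            while t < end:
                on = min(int(rng.uniform(*spec.chore_on_secs)), end - t)
                sd = profile.accel_gain * rng.uniform(*spec.chore_on_sd)
                i0, i1 = t * fs, min((t + on) * fs, n)
                for ax in axes:
                    ax[i0:i1] += rng.normal(0, sd, size=i1 - i0)
                    ax[i0:i1] += _band_noise(i1 - i0, fs, band_f, 0.4,
                                             band_sd, rng)
                t += on + int(rng.uniform(*spec.chore_off_secs))


def render_signals(
    schedule: DaySchedule,
    spec: CohortSpec,
    rng: np.random.Generator,
    profile: SubjectProfile | None = None,
    subject_id: str = "S000",
) -> Recording:
    """Render one 00:00–24:00 day of all five channels from a schedule."""
    if profile is None:
        profile = sample_profile(spec, rng)
    state, level = _day_state_arrays(schedule)
    d0 = schedule.day_start

    # --- accelerometer at 32 Hz ------------------------------------------
    fs_a = 32
    n_a = DAY_SECONDS * fs_a
    sd_map = profile.accel_gain * np.array([
        spec.sleep_accel_sd,
        spec.accel_noise_sd["sedentary"],
        spec.accel_noise_sd["walking"],
        spec.accel_noise_sd["cycling"]])
    sd_sec = sd_map[state]
    sd_samp = np.repeat(sd_sec, fs_a)
    axes = [profile.gravity[i] + rng.normal(0.0, 1.0, n_a) * sd_samp for i in range(3)]
    t_a = np.arange(n_a) / fs_a
    for b0, b1, kind in schedule.activity_bouts:
        if kind == "sedentary":
            continue
        i0 = max(_second_index(b0, d0), 0) * fs_a
        i1 = min(_second_index(b1, d0), DAY_SECONDS) * fs_a
        if i1 <= i0:
            continue
        _exercise_texture(axes, i0, i1, kind, spec, profile, rng)
    # spontaneous wrist gestures happen in every waking state, so their
    # presence does not mark an hour as sedentary
    _add_bursts(axes, np.flatnonzero(state != _STATE_SLEEP),
                spec.gesture_rate_per_hour, profile.accel_gain * spec.gesture_sd,
                spec.gesture_secs, rng)
    _add_bursts(axes, np.flatnonzero(state == _STATE_SLEEP),
                spec.sleep_move_rate_per_hour,
                profile.accel_gain * spec.sleep_move_sd,
                spec.sleep_move_secs, rng)
    chore_segs = _chore_segments(spec, state, level, rng)
    _render_chores(axes, chore_segs, spec, profile, rng)
    chore_sec = (np.concatenate([s for s, _ in chore_segs])
                 if chore_segs else np.array([], dtype=int))

    # --- GSR at 4 Hz ------------------------------------------------------
    fs_g = 4
    n_g = DAY_SECONDS * fs_g
    t_g = np.arange(n_g) / fs_g
    drift_phase = rng.uniform(0, 2 * np.pi)
    tonic = (profile.gsr_baseline
             + spec.gsr_drift_amp * np.sin(2 * np.pi * t_g / (6 * 3600) + drift_phase))
    rate = np.where(state == _STATE_SLEEP, spec.phasic_rate_sleep,
                    spec.phasic_rate_awake).astype(float)
    jl, jh = spec.episode_intensity_jitter
    for e0, e1, lev in schedule.stress_episodes:
        i0 = np.clip(_second_index(e0, d0), 0, DAY_SECONDS)
        i1 = np.clip(_second_index(e1, d0), 0, DAY_SECONDS)
        rate[i0:i1] += spec.phasic_rate_stress[lev] * rng.uniform(jl, jh)
    rate[state == _STATE_WALK] += spec.phasic_rate_exercise["walking"]
    rate[state == _STATE_CYC] += spec.phasic_rate_exercise["cycling"]
    if len(chore_sec):
        rate[chore_sec] += spec.chore_phasic_rate
    rate *= profile.rate_factor
    event_sec = np.flatnonzero(rng.uniform(size=DAY_SECONDS) < rate / 60.0)
    kern_t = np.arange(0, 10, 1.0 / fs_g)
    kernel = (1 - np.exp(-kern_t / spec.phasic_rise)) * np.exp(-kern_t / spec.phasic_decay)
    phasic = np.zeros(n_g)
    if len(event_sec):
        amps = rng.exponential(spec.phasic_amp_mean, size=len(event_sec))
        offs = rng.integers(0, fs_g, size=len(event_sec))
        for s, a, o in zip(event_sec, amps, offs):
            i0 = s * fs_g + int(o)
            seg = min(len(kernel), n_g - i0)
            phasic[i0:i0 + seg] += a * kernel[:seg]
    gsr = np.clip(tonic + profile.gsr_gain * phasic + rng.normal(0, 0.01, n_g), 0.0, None)

    # --- skin temperature at 4 Hz ----------------------------------------
    target = np.full(DAY_SECONDS, profile.temp_base)
    target[state == _STATE_SLEEP] += spec.temp_sleep_delta
    target[state == _STATE_WALK] += spec.temp_exercise_delta["walking"]
    target[state == _STATE_CYC] += spec.temp_exercise_delta["cycling"]
    target[level >= 3] += spec.temp_stress_delta
    from scipy.ndimage import uniform_filter1d
    target = uniform_filter1d(target, size=120, mode="nearest")
    temp = np.repeat(target, fs_g) + rng.normal(0, spec.temp_noise_sd, n_g)

    chans = {
        "accel_x": Channel("accel_x", 32.0, d0, axes[0]),
        "accel_y": Channel("accel_y", 32.0, d0, axes[1]),
        "accel_z": Channel("accel_z", 32.0, d0, axes[2]),
        "gsr": Channel("gsr", 4.0, d0, gsr),
        "skin_temp": Channel("skin_temp", 4.0, d0, temp),
    }
    return Recording(subject_id, chans)


def render_days(
    spec: CohortSpec,
    schedules: list[DaySchedule],
    subject_id: str,
    profile: SubjectProfile,
    rng: np.random.Generator,
) -> Recording:
    """Concatenate consecutive rendered days into one contiguous recording."""
    parts = [render_signals(s, spec, rng, profile=profile, subject_id=subject_id)
             for s in schedules]
    chans = {}
    for name in parts[0].channels:
        vals = np.concatenate([p.channels[name].values for p in parts])
        chans[name] = Channel(name, parts[0].channels[name].sampling_rate,
                              parts[0].channels[name].start_time, vals)
    return Recording(subject_id, chans)


# ---------------------------------------------------------------------------
# self-reports
# ---------------------------------------------------------------------------

def render_reports(
    schedule: DaySchedule,
    noise: SelfReportNoise,
    rng: np.random.Generator,
    subject: str = "S000",
    report_hours: tuple[int, int] = REPORT_HOURS,
    amp_slope: float = 0.35,
) -> tuple[list[HourlyReport], NightReport]:
    """Noisy hourly self-reports and the night report for one schedule.

    Hourly stress = max planted level overlapping the hour (1 if none);
    the activity set holds app-vocabulary tokens for every class with any
    bout overlap, each token independently omitted; whole reports dropped
    at the configured rate.  The night report carries the true bed/get-up
    times plus Gaussian error.
    """
    d0 = schedule.day_start
    reports: list[HourlyReport] = []
    for h in range(report_hours[0], report_hours[1]):
        h0 = d0 + pd.Timedelta(hours=h)
        h1 = h0 + pd.Timedelta(hours=1)
        if h1 <= schedule.wake_time or h0 >= schedule.sleep_onset:
            continue
        if rng.uniform() < noise.report_missing_prob:
            continue
        stress = 1
        for e0, e1, lev in schedule.stress_episodes:
            if e0 < h1 and e1 > h0:
                stress = max(stress, lev)
        classes = {kind for b0, b1, kind in schedule.activity_bouts
                   if b0 < h1 and b1 > h0}
        # irritable appraisal after a short night: the report exceeds the
        # physiological intensity (and vice versa after a long night);
        # self-chosen exercise is not appraised as distress, so amplification
        # applies to non-exercise hours only
        debt = schedule.sleep_debt_hours
        exercising = bool(classes & {"walking", "cycling"})
        if amp_slope and not exercising:
            if debt > 0 and rng.uniform() < min(amp_slope * debt, 0.9):
                stress = min(stress + 1, 5)
            elif debt < 0 and rng.uniform() < min(0.5 * amp_slope * -debt, 0.6):
                stress = max(stress - 1, 1)
        if rng.uniform() < noise.level_flip_prob:  # subjective rating noise
            stress = int(np.clip(stress + rng.choice([-1, 1]), 1, 5))
        tokens = set()
        for cls in sorted(classes):
            tok = APP_TOKENS[cls][rng.integers(0, len(APP_TOKENS[cls]))]
            if rng.uniform() >= noise.activity_omission_prob:
                tokens.add(tok)
        reports.append(HourlyReport(subject, h0, stress, frozenset(tokens)))

    bed = schedule.sleep_onset + pd.Timedelta(
        minutes=float(rng.normal(0, noise.sleep_report_sd)))
    getup = schedule.sleep_offset + pd.Timedelta(
        minutes=float(rng.normal(0, noise.sleep_report_sd)))
    night = NightReport(subject, schedule.sleep_offset.normalize(), bed, getup)
    return reports, night


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    subject_id: str
    profile: SubjectProfile
    schedules: list[DaySchedule]
    hourly_reports: list[HourlyReport]
    night_reports: list[NightReport]


def subject_streams(spec: CohortSpec) -> list[tuple[str, np.random.SeedSequence]]:
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_subjects)
    return [(f"S{i:03d}", ss) for i, ss in enumerate(children)]


def sample_subject(spec: CohortSpec, subject_id: str,
                   ss: np.random.SeedSequence) -> SubjectData:
    """Schedules, profile and reports (no signals) for one subject."""
    ss_prof, ss_sched, ss_rep, _ = ss.spawn(4)
    profile = sample_profile(spec, np.random.default_rng(ss_prof))
    schedules = sample_subject_schedules(spec, subject_id,
                                         np.random.default_rng(ss_sched))
    rng_rep = np.random.default_rng(ss_rep)
    hourly: list[HourlyReport] = []
    nights: list[NightReport] = []
    for sched in schedules:
        reps, night = render_reports(sched, spec.noise, rng_rep, subject=subject_id,
                                     amp_slope=spec.appraisal_amp_slope)
        hourly.extend(reps)
        nights.append(night)
    return SubjectData(subject_id, profile, schedules, hourly, nights)


def render_subject_recording(spec: CohortSpec, data: SubjectData,
                             ss: np.random.SeedSequence) -> Recording:
    """Render the full multi-day recording for one subject."""
    _, _, _, ss_sig = ss.spawn(4)
    rng = np.random.default_rng(ss_sig)
    return render_days(spec, data.schedules, data.subject_id, data.profile, rng)


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write a full cohort to disk: per-subject recording directories,
    ``hourly_reports.csv``, ``night_reports.csv`` and ground-truth CSVs.

    Fully reproducible from ``spec`` (byte-identical on re-run)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hourly_rows, night_rows = [], []
    sched_rows, bout_rows, stress_rows = [], [], []
    for subject_id, ss in subject_streams(spec):
        data = sample_subject(spec, subject_id, ss)
        rec = render_subject_recording(spec, data, ss)
        write_recording(rec, out / subject_id)
        for r in data.hourly_reports:
            hourly_rows.append({
                "subject": r.subject, "hour_start": r.hour_start,
                "stress_1to5": r.stress_1to5,
                "activities": ";".join(sorted(r.activities)),
            })
        for nr in data.night_reports:
            night_rows.append({
                "subject": nr.subject, "date": nr.date.date(),
                "bed_time": nr.bed_time, "getup_time": nr.getup_time,
            })
        for day, s in enumerate(data.schedules):
            sched_rows.append({
                "subject": subject_id, "day": day,
                "sleep_onset": s.sleep_onset, "sleep_offset": s.sleep_offset,
            })
            for b0, b1, kind in s.activity_bouts:
                bout_rows.append({"subject": subject_id, "start": b0,
                                  "end": b1, "activity": kind})
            for e0, e1, lev in s.stress_episodes:
                stress_rows.append({"subject": subject_id, "start": e0,
                                    "end": e1, "level": lev})
    pd.DataFrame(hourly_rows).to_csv(out / "hourly_reports.csv", index=False)
    pd.DataFrame(night_rows).to_csv(out / "night_reports.csv", index=False)
    pd.DataFrame(sched_rows).to_csv(out / "ground_truth_sleep.csv", index=False)
    pd.DataFrame(bout_rows).to_csv(out / "ground_truth_bouts.csv", index=False)
    pd.DataFrame(stress_rows).to_csv(out / "ground_truth_stress.csv", index=False)
    return out


def spec_from_dict(cfg: dict) -> CohortSpec:
    """Build a CohortSpec from a flat config mapping (YAML-friendly)."""
    cfg = dict(cfg)
    noise_keys = {"sleep_report_sd", "activity_omission_prob", "report_missing_prob"}
    noise_cfg = {k: cfg.pop(k) for k in list(cfg) if k in noise_keys}
    spec = CohortSpec(**{k: v for k, v in cfg.items()})
    if noise_cfg:
        spec = replace(spec, noise=SelfReportNoise(**noise_cfg))
    return spec
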