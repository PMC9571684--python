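"""End-to-end drivers tying the modules into cohort-level datasets.

These functions generate a synthetic cohort in memory, compute hourly
physiological features for the reported hours, derive context (from the
self-reports or from the HAR + sleep models) and assemble the stress-event
tables the ablation experiment trains on.  The analysis scripts, the tests
and the CLI all run through here so every entry point exercises the same
code path.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .features import FeatureCatalogue, load_catalogue
from .har import (
    HarModel,
    HarConfig,
    aggregate_minutes,
    build_training_rows,
    hourly_activity_minutes,
    predict_windows,
    train_har,
)
from .sleep import detect_sleep_for_recording
from .stress import assemble_events
from .synthetic import (
    CohortSpec,
    DaySchedule,
    SubjectData,
    planted_schedule,
    render_days,
    render_subject_recording,
    sample_profile,
    sample_subject,
    subject_streams,
)
from .timeseries import Recording, window_at

log = logging.getLogger(__name__)


def subject_hour_features(
    recording: Recording,
    hours: list[pd.Timestamp],
    catalogue: FeatureCatalogue,
) -> pd.DataFrame:
    """Hourly feature rows for the given clock hours of one recording."""
    from .features import extract_hourly_features_batch

    windows = [window_at(recording, h, 3600.0) for h in sorted(hours)]
    df = extract_hourly_features_batch(windows, catalogue)
    df.insert(0, "subject_id", recording.subject_id)
    return df


def selfreport_events(
    spec: CohortSpec,
    catalogue: FeatureCatalogue | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cohort stress-event table with self-reported context.

    Hourly physiology is computed only for reported hours whose date has a
    night report (events without a previous-night report are dropped by the
    alignment rule anyway, so their features are never needed).
    """
    catalogue = catalogue or load_catalogue("hourly")
    all_events, drops_total = [], {}
    for subject_id, ss in subject_streams(spec):
        data = sample_subject(spec, subject_id, ss)
        night_dates = {pd.Timestamp(nr.date).normalize() for nr in data.night_reports}
        reps = [r for r in data.hourly_reports
                if r.hour_start.normalize() in night_dates]
        if not reps:
            continue
        rec = render_subject_recording(spec, data, ss)
        feats = subject_hour_features(rec, [r.hour_start for r in reps], catalogue)
        events, drops = assemble_events(
            feats, reps, "self_report", night_reports=data.night_reports)
        if not events.empty:
            all_events.append(events)
        for k, v in drops.items():
            drops_total[k] = drops_total.get(k, 0) + v
    events = (pd.concat(all_events, ignore_index=True)
              if all_events else pd.DataFrame())
    return events, drops_total


def make_har_training_cohort(
    spec: CohortSpec,
    n_subjects: int,
    seed: int,
    repeats: int = 2,
    catalogue: FeatureCatalogue | None = None,
    subject_prefix: str = "H",
) -> pd.DataFrame:
    """Labelled 15 s feature rows from subjects with a fixed bout pattern.

    Each subject's day interleaves sedentary, walking and cycling bouts
    (10 / 10 / 10 min with sedentary gaps, ``repeats`` times), standing in
    for a video-annotated activity benchmark.  Exercise look-alike chores
    are disabled: a labelled benchmark has separable annotated activities,
    whereas look-alike motion is a free-living deployment phenomenon (the
    recognizer will mislabel some of it there, which is part of what the
    machine-learned-context experiment measures).
    """
    from dataclasses import replace
    spec = replace(spec, chore_mimic_prob=0.0)
    catalogue = catalogue or load_catalogue("har")
    root = np.random.SeedSequence(seed)
    rows = []
    for i, ss in enumerate(root.spawn(n_subjects)):
        subject = f"{subject_prefix}{i:03d}"
        rng = np.random.default_rng(ss)
        profile = sample_profile(spec, rng)
        day0 = pd.Timestamp(spec.start_date).normalize()
        wake = day0 + pd.Timedelta(hours=8)
        t = wake
        bouts = []
        for _ in range(repeats):
            for kind, mins in (("sedentary", 10), ("walking", 10),
                               ("sedentary", 5), ("cycling", 10),
                               ("sedentary", 5)):
                bouts.append((t, t + pd.Timedelta(minutes=mins), kind))
                t += pd.Timedelta(minutes=mins)
        end = t
        sched = DaySchedule(day0, day0 + pd.Timedelta(hours=23),
                            day0 + pd.Timedelta(hours=31), bouts, [])
        from .synthetic import render_signals
        rec = render_signals(sched, spec, rng, profile=profile, subject_id=subject)
        sub = rec.slice(wake, end)
        df = build_training_rows(sub, bouts, catalogue)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def ml_events(
    spec: CohortSpec,
    har_model: HarModel,
    hourly_catalogue: FeatureCatalogue | None = None,
    har_catalogue: FeatureCatalogue | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cohort stress-event table with machine-learned context.

    Activity minutes come from the HAR model's 7.5 s probability timeline
    aggregated per minute and per hour; sleep context from the detected
    rest period of the preceding 13:00 → 13:00 day window.  First-day
    events have no preceding overnight window and drop out.
    """
    hourly_catalogue = hourly_catalogue or load_catalogue("hourly")
    har_catalogue = har_catalogue or load_catalogue("har")
    all_events, drops_total = [], {}
    for subject_id, ss in subject_streams(spec):
        data = sample_subject(spec, subject_id, ss)
        reps = [r for r in data.hourly_reports
                if r.hour_start.normalize() > pd.Timestamp(spec.start_date).normalize()]
        if not reps:
            continue
        rec = render_subject_recording(spec, data, ss)
        hours = sorted({r.hour_start for r in reps})
        feats = subject_hour_features(rec, hours, hourly_catalogue)

        act_parts = []
        for h in hours:
            h_end = min(h + pd.Timedelta(seconds=3615), rec.end_time)
            probs = predict_windows(har_model, rec.slice(h, h_end), har_catalogue)
            probs = probs[probs["window_start"] < h + pd.Timedelta(hours=1)]
            mins = aggregate_minutes(probs)
            act_parts.append(hourly_activity_minutes(mins))
        act = (pd.concat(act_parts, ignore_index=True)
               if act_parts else pd.DataFrame())
        if not act.empty:
            act.insert(0, "subject_id", subject_id)

        sleep_rows = []
        for est in detect_sleep_for_recording(rec):
            sleep_rows.append({
                "subject_id": subject_id,
                "day_window_start": est.day_window_start,
                "onset": est.onset, "offset": est.offset,
                "status": est.status,
            })
        sleep_df = pd.DataFrame(sleep_rows)

        events, drops = assemble_events(
            feats, reps, "ml", activity_minutes=act, sleep_estimates=sleep_df)
        if not events.empty:
            all_events.append(events)
        for k, v in drops.items():
            drops_total[k] = drops_total.get(k, 0) + v
    events = (pd.concat(all_events, ignore_index=True)
              if all_events else pd.DataFrame())
    return events, drops_total


def train_default_har_model(
    spec: CohortSpec,
    n_subjects: int = 6,
    seed: int = 17,
    config: HarConfig | None = None,
) -> HarModel:
    """Train a HAR model on a small synthetic labelled cohort."""
    rows = make_har_training_cohort(spec, n_subjects, seed, repeats=1)
    return train_har(rows, config or HarConfig(depth_grid=(4, 6), seed=seed))


def planted_night_recording(
    spec: CohortSpec,
    seed: int,
    bed_hour: float = 23.0,
    getup_hour: float = 7.0,
    subject_id: str = "N000",
) -> tuple[Recording, pd.Timestamp, pd.Timestamp]:
    """One 13:00 → 13:00 day window with a planted rest period.

    Returns (day-window recording, true onset, true offset); the onset is
    on the first rendered day, the offset on the second.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    day0 = pd.Timestamp(spec.start_date).normalize()
    day1 = day0 + pd.Timedelta(days=1)
    onset = day0 + pd.Timedelta(hours=bed_hour)
    offset = day1 + pd.Timedelta(hours=getup_hour)
    profile = sample_profile(spec, rng)
    s0 = planted_schedule(spec, day0, day0 + pd.Timedelta(hours=7), onset, offset, rng)
    s1 = planted_schedule(spec, day1, offset, day1 + pd.Timedelta(hours=23),
                          day1 + pd.Timedelta(hours=31), rng)
    rec = render_days(spec, [s0, s1], subject_id, profile, rng)
    win = rec.slice(day0 + pd.Timedelta(hours=13), day1 + pd.Timedelta(hours=13))
    return win, onset, offset
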