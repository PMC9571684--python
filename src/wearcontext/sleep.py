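"""Unsupervised nightly rest-period detection from raw wrist accelerometry.

Pipeline, applied to one 24 h day window (anchored at 13:00 so the night
sits in the middle):

1. **Activity index** — per minute, the square root of the mean per-axis
   variance of the 32 Hz accelerometer over the trailing 10 min window.
2. **Smooth + scale** — third-order zero-phase Butterworth low-pass on the
   minute series (cutoff 0.04 cycles/epoch ≈ 25 min smoothing) followed by
   min–max scaling to [0, 1] within the day window.
3. **Sleep/wake scores** — a Cole-style weighted moving sum over epochs
   t−4 … t+2 of the scaled activity (weights 404, 598, 326, 441, 1408,
   508, 350 × 1e−5, calibration gain 200); score < 1 ⇒ sleep.  The scores
   are diagnostic: they gate whether a candidate segment counts as rest.
4. **Segmentation** — the exact least-squares two-change-point split of
   the log-transformed score series (log compresses daytime exercise
   spikes so the night-level shift dominates the cost) with the two change
   points at least 5 h apart; the enclosed segment is the rest period when
   its epochs are predominantly scored asleep and its mean scaled activity
   is below both flanks.

The two-change-point search is solved exactly (vectorized enumeration over
all admissible pairs via prefix sums); at minute resolution a day window
has ≤ 1440 epochs, so exhaustive minimization is cheap and removes any
dependence on greedy split ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .timeseries import ACCEL_CHANNELS, Recording, iter_day_windows
from .synthetic import NightReport

#: Cole-style weight profile applied to epochs t-4 .. t+2
COLE_WEIGHTS = np.array([404, 598, 326, 441, 1408, 508, 350]) * 1e-5
#: calibration gain so typical scaled wake activity scores above 1
COLE_GAIN = 200.0
#: sleep/wake decision threshold on the score
SCORE_THRESHOLD = 1.0
#: minimum separation of the two change points: 5 h of 1 min epochs
MIN_GAP_EPOCHS = 300
#: low-pass cutoff for the epoch series, cycles per epoch
EPOCH_LP_CUTOFF = 0.04
#: the enclosed segment counts as rest when at least this fraction of its
#: epochs is scored asleep
MIN_SLEEP_SCORE_FRACTION = 0.5
#: additive offset before the log transform of the score series that the
#: change-point search runs on (keeps the log finite at zero activity)
SEGMENT_LOG_OFFSET = 0.05


@dataclass
class ActivityIndexSeries:
    """Minute-resolution motion summary of one day window."""

    epoch_start: pd.DatetimeIndex
    raw: np.ndarray
    scaled: np.ndarray | None = None
    step_seconds: float = 60.0


@dataclass
class SleepEstimate:
    """Detected rest period for one 13:00 → 13:00 day window."""

    day_window_start: pd.Timestamp
    onset: pd.Timestamp | None
    offset: pd.Timestamp | None
    status: str = "ok"  # "ok" | "no_sleep_detected"
    sleep_score_fraction: float = float("nan")
    scores: np.ndarray | None = field(default=None, repr=False)

    @property
    def duration_minutes(self) -> float:
        if self.status != "ok":
            return float("nan")
        return (self.offset - self.onset).total_seconds() / 60.0


def activity_index(
    recording: Recording,
    window_seconds: float = 600.0,
    step_seconds: float = 60.0,
) -> ActivityIndexSeries:
    """Rolling ``sqrt(mean per-axis variance)`` of the accelerometer.

    One value per ``step_seconds``; the value timestamped at minute ``m``
    summarizes the trailing ``window_seconds`` ending at the close of that
    minute.  Epochs whose window contains missing samples are NaN.
    """
    fs = 32
    x = np.stack([recording[c].values for c in ACCEL_CHANNELS])
    n = x.shape[1]
    w = int(window_seconds * fs)
    step = int(step_seconds * fs)
    if n < w:
        raise ValueError("need at least one full window of data")
    finite = np.isfinite(x)
    # center each axis before the cumulative sums: variance is shift
    # invariant and the subtraction avoids catastrophic cancellation
    mu = np.nanmean(np.where(finite, x, np.nan), axis=1, keepdims=True)
    xf = np.where(finite, x - mu, 0.0)
    c1 = np.cumsum(xf, axis=1)
    c2 = np.cumsum(xf * xf, axis=1)
    cn = np.cumsum(finite, axis=1)
    c1 = np.concatenate([np.zeros((3, 1)), c1], axis=1)
    c2 = np.concatenate([np.zeros((3, 1)), c2], axis=1)
    cn = np.concatenate([np.zeros((3, 1)), cn], axis=1)
    ends = np.arange(w, n + 1, step)
    starts = ends - w
    s1 = c1[:, ends] - c1[:, starts]
    s2 = c2[:, ends] - c2[:, starts]
    sn = cn[:, ends] - cn[:, starts]
    complete = (sn == w).all(axis=0)
    with np.errstate(invalid="ignore"):
        var = s2 / w - (s1 / w) ** 2
    val = np.sqrt(np.maximum(var.mean(axis=0), 0.0))
    val[~complete] = np.nan
    start = recording.start_time
    stamps = pd.DatetimeIndex(
        start + pd.Timedelta(seconds=1) * (ends / fs - step_seconds))
    return ActivityIndexSeries(stamps, val, step_seconds=step_seconds)


def smooth_and_scale(series: ActivityIndexSeries) -> ActivityIndexSeries:
    """Low-pass the raw epoch series and min–max scale it to [0, 1].

    A constant series scales to all zeros.  Internal missing epochs are
    linearly interpolated before filtering; an all-missing series is an
    error.
    """
    raw = series.raw.astype(np.float64)
    good = np.isfinite(raw)
    if not good.any():
        raise ValueError("all epochs missing")
    vals = raw.copy()
    if not good.all():
        idx = np.arange(len(vals))
        vals[~good] = np.interp(idx[~good], idx[good], vals[good])
    if len(vals) > 21:  # enough epochs for stable zero-phase filtering
        sos = _sig.butter(3, EPOCH_LP_CUTOFF * 2, btype="low", output="sos")
        vals = _sig.sosfiltfilt(sos, vals)
    lo, hi = float(np.min(vals)), float(np.max(vals))
    scaled = np.zeros_like(vals) if hi - lo < 1e-12 else (vals - lo) / (hi - lo)
    return ActivityIndexSeries(series.epoch_start, raw, scaled, series.step_seconds)


def sleep_wake_scores(
    scaled: np.ndarray,
    gain: float = COLE_GAIN,
    threshold: float = SCORE_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Cole-style per-epoch scores and binary sleep calls.

    ``score_t = gain * sum_{j=-4..+2} w_j * a_{t+j}``; epochs outside the
    series contribute nothing (edge truncation).  ``call`` is True where
    the epoch is scored asleep (score below threshold).
    """
    a = np.asarray(scaled, dtype=np.float64)
    pad = np.concatenate([np.zeros(4), a, np.zeros(2)])
    # correlation with the weight profile: w[0] hits epoch t-4
    score = gain * np.convolve(pad, COLE_WEIGHTS[::-1], mode="valid")
    return score, score < threshold


def _segment_cost_terms(a: np.ndarray):
    s1 = np.concatenate([[0.0], np.cumsum(a)])
    s2 = np.concatenate([[0.0], np.cumsum(a * a)])

    def sse(i, j):
        """Within-segment sum of squared deviations for [i, j); vectorized."""
        n = j - i
        s = s1[j] - s1[i]
        q = s2[j] - s2[i]
        return q - s * s / np.maximum(n, 1)

    return sse


def best_two_changepoints(
    a: np.ndarray, min_gap: int = MIN_GAP_EPOCHS
) -> tuple[int, int] | None:
    """Exact least-squares two-change-point split of ``a``.

    Returns the pair ``(i, j)`` (segment boundaries, ``j - i >= min_gap``,
    all three segments non-empty) minimizing the total within-segment sum
    of squared deviations, or None when no admissible pair exists.
    """
    a = np.asarray(a, dtype=np.float64)
    n = len(a)
    if n < min_gap + 2:
        return None
    sse = _segment_cost_terms(a)
    i_vals = np.arange(1, n - min_gap)
    j_vals = np.arange(1 + min_gap, n)
    left = sse(0, i_vals)
    right = sse(j_vals, n)
    I = i_vals[:, None]
    J = j_vals[None, :]
    mid = sse(I, J)
    total = left[:, None] + mid + right[None, :]
    total = np.where(J - I >= min_gap, total, np.inf)
    flat = np.argmin(total)
    ii, jj = np.unravel_index(flat, total.shape)
    if not np.isfinite(total[ii, jj]):
        return None
    return int(i_vals[ii]), int(j_vals[jj])


def detect_sleep_period(
    day_recording: Recording,
    day_window_start: pd.Timestamp | None = None,
) -> SleepEstimate:
    """Detect the rest period inside one 13:00 → 13:00 day window.

    The enclosed segment between the two change points is accepted as the
    rest period when its mean scaled activity is below both flanking
    segments and at least half of its epochs are scored asleep; otherwise
    the result is ``no_sleep_detected``.
    """
    if day_window_start is None:
        day_window_start = day_recording.start_time
    if day_recording.duration < 18 * 3600:
        raise ValueError("day window needs at least 18 h of data")
    series = smooth_and_scale(activity_index(day_recording))
    a = series.scaled
    scores, calls = sleep_wake_scores(a)
    # Segment the log of the score series: the scores fold in the Cole
    # weighting, and the log compresses exercise spikes so the change points
    # respond to the wake/sleep level shift rather than to daytime bursts.
    cp = best_two_changepoints(np.log(scores + SEGMENT_LOG_OFFSET))
    no_sleep = SleepEstimate(day_window_start, None, None, "no_sleep_detected",
                             scores=scores)
    if cp is None:
        return no_sleep
    i, j = cp
    mid_mean = float(np.mean(a[i:j]))
    left_mean = float(np.mean(a[:i]))
    right_mean = float(np.mean(a[j:]))
    frac_asleep = float(np.mean(calls[i:j]))
    if mid_mean >= left_mean or mid_mean >= right_mean:
        no_sleep.sleep_score_fraction = frac_asleep
        return no_sleep
    if frac_asleep < MIN_SLEEP_SCORE_FRACTION:
        no_sleep.sleep_score_fraction = frac_asleep
        return no_sleep
    onset = series.epoch_start[i]
    offset = series.epoch_start[j]
    return SleepEstimate(day_window_start, onset, offset, "ok",
                         sleep_score_fraction=frac_asleep, scores=scores)


def detect_sleep_for_recording(
    recording: Recording, anchor_hour: int = 13
) -> list[SleepEstimate]:
    """Run detection over every 13:00 → 13:00 window of a multi-day recording."""
    out = []
    for start, sub in iter_day_windows(recording, anchor_hour=anchor_hour):
        out.append(detect_sleep_period(sub, day_window_start=start))
    return out


def compare_sleep(
    estimate: SleepEstimate, report: NightReport
) -> dict[str, float] | None:
    """Signed deltas (self-report minus detected), in minutes.

    Positive values mean the self-report is later (onset/offset) or longer
    (duration) than the detector's estimate.  Returns None for nights the
    detector flagged ``no_sleep_detected`` (excluded from summaries).
    """
    if estimate.status != "ok":
        return None
    onset_d = (report.bed_time - estimate.onset).total_seconds() / 60.0
    offset_d = (report.getup_time - estimate.offset).total_seconds() / 60.0
    rep_dur = (report.getup_time - report.bed_time).total_seconds() / 60.0
    return {
        "onset_delta": onset_d,
        "offset_delta": offset_d,
        "duration_delta": rep_dur - estimate.duration_minutes,
    }


def summarize_deltas(deltas: list[dict[str, float]]) -> dict[str, float]:
    """Cohort-level mean and sd of the absolute deltas."""
    out = {}
    for key in ("onset_delta", "offset_delta", "duration_delta"):
        vals = np.abs([d[key] for d in deltas])
        out[f"abs_{key}_mean"] = float(np.mean(vals))
        out[f"abs_{key}_sd"] = float(np.std(vals))
    return out
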