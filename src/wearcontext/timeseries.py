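"""Core data model for multichannel wrist-wearable recordings.

A :class:`Recording` holds five uniformly sampled channels — three
accelerometer axes at 32 Hz plus galvanic skin response (GSR) and skin
temperature at 4 Hz — for one subject.  Channels are stored as plain numpy
arrays with an explicit start time and sampling rate; sample ``i`` of a
channel is taken at ``start_time + i / sampling_rate``.  All intervals in
this package are half-open ``[start, end)`` and timestamps mark the left
edge of the interval they describe.

Storage format is one CSV per channel (``timestamp,value``, ISO-8601 UTC
timestamps) plus a small JSON metadata file naming the subject and the
channel → sampling-rate map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

ACCEL_CHANNELS = ("accel_x", "accel_y", "accel_z")
SLOW_CHANNELS = ("gsr", "skin_temp")
CHANNEL_NAMES = ACCEL_CHANNELS + SLOW_CHANNELS

#: default sampling rates (Hz) per channel
CHANNEL_RATES: dict[str, float] = {
    "accel_x": 32.0,
    "accel_y": 32.0,
    "accel_z": 32.0,
    "gsr": 4.0,
    "skin_temp": 4.0,
}

#: an hour (or window) is usable only if every channel has at least this
#: fraction of its expected samples present (non-NaN)
USABLE_FRACTION = 0.80


class MissingChannelError(KeyError):
    """A required channel file/entry is absent from a recording."""


class FormatError(ValueError):
    """Channel data violates the uniform-sampling contract."""


@dataclass
class Channel:
    """One uniformly sampled signal.

    NaN values mark explicitly missing samples; the time base stays uniform.
    """

    name: str
    sampling_rate: float
    start_time: pd.Timestamp
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.values = np.asarray(self.values, dtype=np.float64)
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Length of the channel in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=self.duration)

    def timestamps(self) -> pd.DatetimeIndex:
        step = pd.Timedelta(seconds=1.0 / self.sampling_rate)
        return pd.DatetimeIndex(self.start_time + step * np.arange(self.n_samples))

    def slice_seconds(self, t0: float, t1: float) -> np.ndarray:
        """Samples in ``[start_time + t0, start_time + t1)`` (seconds offsets)."""
        i0 = int(round(t0 * self.sampling_rate))
        i1 = int(round(t1 * self.sampling_rate))
        return self.values[max(i0, 0): i1]


@dataclass
class Recording:
    """One subject's multichannel signal set."""

    subject_id: str
    channels: dict[str, Channel] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Channel:
        try:
            return self.channels[name]
        except KeyError:
            raise MissingChannelError(name) from None

    @property
    def start_time(self) -> pd.Timestamp:
        return max(c.start_time for c in self.channels.values())

    @property
    def end_time(self) -> pd.Timestamp:
        return min(c.end_time for c in self.channels.values())

    @property
    def duration(self) -> float:
        """Common covered span in seconds (may be negative if disjoint)."""
        return (self.end_time - self.start_time).total_seconds()

    def require_complete(self) -> None:
        missing = [n for n in CHANNEL_NAMES if n not in self.channels]
        if missing:
            raise MissingChannelError(", ".join(missing))

    def slice(self, start: pd.Timestamp, end: pd.Timestamp) -> "Recording":
        """Sub-recording covering ``[start, end)``; sample-aligned channels."""
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        out: dict[str, Channel] = {}
        for name, ch in self.channels.items():
            t0 = (start - ch.start_time).total_seconds()
            t1 = (end - ch.start_time).total_seconds()
            vals = ch.slice_seconds(t0, t1)
            out[name] = Channel(name, ch.sampling_rate, start, vals)
        return Recording(self.subject_id, out)


@dataclass
class Window:
    """A half-open slice ``[start, start + duration)`` of a recording."""

    start: pd.Timestamp
    duration: float
    samples: dict[str, np.ndarray]

    def usable(self, min_fraction: float = USABLE_FRACTION) -> bool:
        """True when every channel has >= ``min_fraction`` non-NaN samples."""
        for vals in self.samples.values():
            if len(vals) == 0:
                return False
            if np.mean(np.isfinite(vals)) < min_fraction:
                return False
        return True


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path: str | Path) -> None:
    """Write one CSV per channel plus ``metadata.json`` into ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": recording.subject_id,
        "channels": {},
    }
    for name, ch in recording.channels.items():
        meta["channels"][name] = {
            "sampling_rate": ch.sampling_rate,
            "start_time": _iso(ch.start_time),
            "n_samples": ch.n_samples,
        }
        _write_channel_csv(path / f"{name}.csv", ch)
    (path / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def _iso(ts: pd.Timestamp) -> str:
    return np.datetime_as_string(np.datetime64(ts, "us"), unit="us", timezone="naive") + "Z"


def _write_channel_csv(fp: Path, ch: Channel) -> None:
    step_us = int(round(1e6 / ch.sampling_rate))
    t0 = np.datetime64(ch.start_time, "us")
    stamps = t0 + np.arange(ch.n_samples) * np.timedelta64(step_us, "us")
    stamp_str = np.datetime_as_string(stamps, unit="us", timezone="naive")
    vals = np.char.mod("%.6f", ch.values)
    with open(fp, "w") as fh:
        fh.write("timestamp,value\n")
        body = np.char.add(np.char.add(stamp_str, "Z,"), vals)
        fh.write("\n".join(body.tolist()))
        fh.write("\n")


def read_recording(path: str | Path, require_complete: bool = True) -> Recording:
    """Load a recording directory written by :func:`write_recording`.

    Timestamps are checked for uniformity: deviation beyond one sample step
    from the implied uniform grid raises :class:`FormatError`.
    """
    path = Path(path)
    meta_fp = path / "metadata.json"
    if not meta_fp.exists():
        raise FormatError(f"no metadata.json in {path}")
    meta = json.loads(meta_fp.read_text())
    channels: dict[str, Channel] = {}
    for name, info in meta["channels"].items():
        fp = path / f"{name}.csv"
        if not fp.exists():
            raise MissingChannelError(name)
        channels[name] = _read_channel_csv(fp, name, float(info["sampling_rate"]))
    rec = Recording(meta["subject_id"], channels)
    if require_complete:
        rec.require_complete()
    return rec


def _read_channel_csv(fp: Path, name: str, rate: float) -> Channel:
    df = pd.read_csv(fp)
    stamps = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce", utc=True)
    ok = stamps.notna()
    if not ok.all():  # unparseable rows are rejected
        df = df[ok]
        stamps = stamps[ok]
    stamps = stamps.dt.tz_localize(None)
    if len(df) == 0:
        raise FormatError(f"{fp}: no valid rows")
    t0 = stamps.iloc[0]
    rel = (stamps - t0).dt.total_seconds().to_numpy()
    expected = np.arange(len(rel)) / rate
    if np.max(np.abs(rel - expected)) > 1.0 / rate:  # beyond 1-sample jitter
        raise FormatError(f"{fp}: non-uniform timestamps for stated rate {rate} Hz")
    return Channel(name, rate, t0, df["value"].to_numpy(dtype=np.float64))


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def window_at(recording: Recording, start: pd.Timestamp, duration: float) -> Window:
    """Materialize the window ``[start, start + duration)`` of a recording."""
    samples: dict[str, np.ndarray] = {}
    for name, ch in recording.channels.items():
        t0 = (start - ch.start_time).total_seconds()
        samples[name] = ch.slice_seconds(t0, t0 + duration)
    return Window(start, duration, samples)


_window_at = window_at


def slide_windows(
    recording: Recording,
    duration: float = 15.0,
    overlap_fraction: float = 0.5,
) -> list[Window]:
    """Sliding windows from the recording start; only complete windows.

    With ``duration=15`` and ``overlap=0.5`` the stride is 7.5 s, matching
    the HAR segmentation (one window start every 7.5 s).
    """
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    stride = duration * (1.0 - overlap_fraction)
    total = recording.duration
    out: list[Window] = []
    n = 0
    while n * stride + duration <= total + 1e-9:
        start = recording.start_time + pd.Timedelta(seconds=n * stride)
        w = _window_at(recording, start, duration)
        if all(
            len(w.samples[c]) == int(round(duration * recording.channels[c].sampling_rate))
            for c in recording.channels
        ):
            out.append(w)
        n += 1
    return out


def hour_windows(recording: Recording) -> list[Window]:
    """Non-overlapping clock-aligned hourly windows ``[HH:00, HH+1:00)``.

    Partial leading/trailing hours are dropped.
    """
    start = recording.start_time.ceil("h")
    end = recording.end_time
    out: list[Window] = []
    t = start
    while t + pd.Timedelta(hours=1) <= end:
        out.append(_window_at(recording, t, 3600.0))
        t += pd.Timedelta(hours=1)
    return out


# ---------------------------------------------------------------------------
# shared signal operators
# ---------------------------------------------------------------------------

def bandpass(
    values: Sequence[float],
    sampling_rate: float,
    order: int = 4,
    low: float = 0.3,
    high: float = 15.0,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward filtering).

    ``high`` must stay below the Nyquist frequency; callers that cannot
    guarantee this must cap it themselves (e.g. at 0.99 x Nyquist).
    Output has the same length as the input.
    """
    nyq = sampling_rate / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = _sig.butter(order, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    return _sig.sosfiltfilt(sos, np.asarray(values, dtype=np.float64))


def euclidean_norm(x: Sequence[float], y: Sequence[float], z: Sequence[float]) -> np.ndarray:
    """Element-wise ``sqrt(x^2 + y^2 + z^2)`` of the three accelerometer axes."""
    x, y, z = (np.asarray(a, dtype=np.float64) for a in (x, y, z))
    if not (len(x) == len(y) == len(z)):
        raise ValueError("axis length mismatch")
    return np.sqrt(x * x + y * y + z * z)


def iter_day_windows(
    recording: Recording, anchor_hour: int = 13
) -> Iterator[tuple[pd.Timestamp, Recording]]:
    """Yield (window_start, sub-recording) for each 24 h window anchored at
    ``anchor_hour`` local clock time (default 13:00 → 13:00 next day)."""
    first = recording.start_time.normalize() + pd.Timedelta(hours=anchor_hour)
    if first < recording.start_time:
        first += pd.Timedelta(days=1)
    t = first
    while t + pd.Timedelta(hours=24) <= recording.end_time:
        yield t, recording.slice(t, t + pd.Timedelta(hours=24))
        t += pd.Timedelta(days=1)
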