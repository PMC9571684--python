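"""Windowed feature extraction for hourly physiology and 15 s HAR windows.

Two fixed, documented feature catalogues define the file contracts:

* ``hourly`` — 73 named statistics applied to each of the five raw signals
  (accel_x, accel_y, accel_z, gsr, skin_temp), giving 365 values per hour.
  Hourly features are computed on the raw signals, without band-passing.
* ``har``    — statistics applied to seven derived series per 15 s window:
  the four band-passed accelerometer series (x, y, z and their Euclidean
  norm, order-4 Butterworth 0.3–15 Hz, norm computed *before* filtering)
  get time- and frequency-domain features; the phasic and tonic components
  of the z-normalized GSR and the raw skin temperature get time-domain
  features only.  The expansion totals exactly 228 values per window.

Catalogues are CSV data files shipped with the package; users may point the
extractors at their own lists, but cardinality (73 / 228) is asserted at
load time because downstream tables depend on the layout.

Every feature is a vectorized function ``f(X, fs) -> 1-D array`` over a 2-D
batch ``X`` of shape (n_windows, n_samples); single-window extraction is the
n=1 special case.  Degenerate inputs (constant series, zero power spectra)
map to 0 rather than NaN so feature tables stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .timeseries import (
    ACCEL_CHANNELS,
    Window,
    bandpass,
    euclidean_norm,
)

_EPS = 1e-12

HOURLY_SIGNALS = ("accel_x", "accel_y", "accel_z", "gsr", "skin_temp")

#: sampling rate of each derived HAR series
HAR_SERIES_RATES = {
    "accel_x": 32.0,
    "accel_y": 32.0,
    "accel_z": 32.0,
    "accel_norm": 32.0,
    "gsr_phasic": 4.0,
    "gsr_tonic": 4.0,
    "skin_temp": 4.0,
}

N_HOURLY_FEATURES = 73
N_HAR_FEATURES = 228


# ---------------------------------------------------------------------------
# time-domain features
# ---------------------------------------------------------------------------

# Per-batch memo for expensive shared intermediates (centered moments, PSD,
# sorted rows).  Entries hold a strong reference to the keyed array — the id
# of a garbage-collected array can be recycled, so a hit is only valid while
# the original array is provably alive and identical.  The extractors clear
# the cache after each series batch.
_CACHE: dict = {}


def _memo(tag, X, builder):
    key = (tag, id(X))
    hit = _CACHE.get(key)
    if hit is not None and hit[0] is X:
        return hit[1]
    payload = builder()
    _CACHE[key] = (X, payload)
    return payload


def _moments(X):
    def build():
        mu = X.mean(axis=1, keepdims=True)
        d = X - mu
        d2 = d * d
        return (mu[:, 0], d, d2.mean(axis=1), d2)
    return _memo("mom", X, build)[:3]


def _moments4(X):
    mu, d, m2 = _moments(X)
    d2 = _memo("mom", X, lambda: None)[3]

    def build():
        return ((d2 * d).mean(axis=1), (d2 * d2).mean(axis=1))
    m3, m4 = _memo("mom4", X, build)
    return mu, m2, m3, m4


def _f_mean(X, fs):
    return X.mean(axis=1)


def _f_std(X, fs):
    return np.sqrt(_moments(X)[2])


def _f_variance(X, fs):
    return _moments(X)[2]


def _f_minimum(X, fs):
    return X.min(axis=1)


def _f_maximum(X, fs):
    return X.max(axis=1)


def _sorted(X):
    return _memo("sort", X, lambda: np.sort(X, axis=1))


def _sorted_quantile(Xs, q):
    """Linear-interpolation quantile on pre-sorted rows."""
    t = Xs.shape[1]
    pos = q * (t - 1)
    lo = int(np.floor(pos))
    frac = pos - lo
    if lo + 1 >= t:
        return Xs[:, -1]
    return Xs[:, lo] * (1 - frac) + Xs[:, lo + 1] * frac


def _f_median(X, fs):
    return _sorted_quantile(_sorted(X), 0.5)


def _f_range(X, fs):
    return np.ptp(X, axis=1)


def _f_rms(X, fs):
    return np.sqrt(np.mean(X * X, axis=1))


def _f_abs_energy(X, fs):
    return np.sum(X * X, axis=1)


def _f_skewness(X, fs):
    _, m2, m3, _ = _moments4(X)
    return np.where(m2 > _EPS, m3 / np.maximum(m2, _EPS) ** 1.5, 0.0)


def _f_kurtosis(X, fs):
    _, m2, _, m4 = _moments4(X)
    return np.where(m2 > _EPS, m4 / np.maximum(m2, _EPS) ** 2 - 3.0, 0.0)


def _f_zero_crossings(X, fs):
    return np.sum(np.signbit(X[:, 1:]) != np.signbit(X[:, :-1]), axis=1).astype(float)


def _f_mean_abs_change(X, fs):
    return np.mean(np.abs(np.diff(X, axis=1)), axis=1)


def _f_mean_change(X, fs):
    return (X[:, -1] - X[:, 0]) / max(X.shape[1] - 1, 1)


def _f_abs_max(X, fs):
    return np.max(np.abs(X), axis=1)


def _quantile(q):
    def f(X, fs):
        return _sorted_quantile(_sorted(X), q)
    return f


def _f_iqr(X, fs):
    Xs = _sorted(X)
    return _sorted_quantile(Xs, 0.75) - _sorted_quantile(Xs, 0.25)


def _autocorr(lag):
    def f(X, fs):
        _, d, m2 = _moments(X)
        if X.shape[1] <= lag:
            return np.zeros(X.shape[0])
        num = np.mean(d[:, lag:] * d[:, :-lag], axis=1)
        return np.where(m2 > _EPS, num / np.maximum(m2, _EPS), 0.0)
    return f


def _f_count_above_mean(X, fs):
    mu = X.mean(axis=1, keepdims=True)
    return np.sum(X > mu, axis=1).astype(float)


def _f_count_below_mean(X, fs):
    mu = X.mean(axis=1, keepdims=True)
    return np.sum(X < mu, axis=1).astype(float)


def _f_sum_abs(X, fs):
    return np.sum(np.abs(X), axis=1)


def _f_sum_values(X, fs):
    return X.sum(axis=1)


def _f_mean_abs_dev(X, fs):
    mu = X.mean(axis=1, keepdims=True)
    return np.mean(np.abs(X - mu), axis=1)


def _f_median_abs_dev(X, fs):
    med = np.median(X, axis=1, keepdims=True)
    return np.median(np.abs(X - med), axis=1)


def _f_cid_ce(X, fs):
    return np.sqrt(np.sum(np.diff(X, axis=1) ** 2, axis=1))


def _f_number_peaks_3(X, fs):
    """Count samples strictly greater than their 3 neighbours on each side."""
    n, t = X.shape
    if t < 7:
        return np.zeros(n)
    core = X[:, 3:t - 3]
    ok = np.ones(core.shape, dtype=bool)
    for k in range(1, 4):
        ok &= core > X[:, 3 - k:t - 3 - k]
        ok &= core > X[:, 3 + k:t - 3 + k]
    return ok.sum(axis=1).astype(float)


def _f_binned_entropy_10(X, fs):
    out = np.zeros(X.shape[0])
    for i, row in enumerate(X):
        counts, _ = np.histogram(row, bins=10)
        p = counts[counts > 0] / len(row)
        out[i] = -np.sum(p * np.log(p))
    return out


def _f_first_location_of_max(X, fs):
    return np.argmax(X, axis=1) / X.shape[1]


def _f_last_location_of_max(X, fs):
    return (X.shape[1] - 1 - np.argmax(X[:, ::-1], axis=1)) / X.shape[1]


def _f_first_location_of_min(X, fs):
    return np.argmin(X, axis=1) / X.shape[1]


def _f_last_location_of_min(X, fs):
    return (X.shape[1] - 1 - np.argmin(X[:, ::-1], axis=1)) / X.shape[1]


def _ratio_beyond_sigma(r):
    def f(X, fs):
        _, d, m2 = _moments(X)
        sd = np.sqrt(m2)[:, None]
        return np.mean(np.abs(d) > r * np.maximum(sd, _EPS), axis=1)
    return f


def _longest_run(mask_row: np.ndarray) -> int:
    if not mask_row.any():
        return 0
    padded = np.concatenate(([False], mask_row, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int(np.max(edges[1::2] - edges[0::2]))


def _f_longest_strike_above_mean(X, fs):
    mu = X.mean(axis=1, keepdims=True)
    return np.array([_longest_run(row) for row in X > mu], dtype=float)


def _f_longest_strike_below_mean(X, fs):
    mu = X.mean(axis=1, keepdims=True)
    return np.array([_longest_run(row) for row in X < mu], dtype=float)


def _f_variation_coefficient(X, fs):
    mu = X.mean(axis=1)
    sd = X.std(axis=1)
    return np.where(np.abs(mu) > _EPS, sd / np.where(np.abs(mu) > _EPS, mu, 1.0), 0.0)


def _f_energy_ratio_first_half(X, fs):
    half = X.shape[1] // 2
    tot = np.sum(X * X, axis=1)
    return np.sum(X[:, :half] ** 2, axis=1) / np.maximum(tot, _EPS)


def _f_index_mass_quantile_50(X, fs):
    a = np.abs(X)
    cs = np.cumsum(a, axis=1)
    tot = cs[:, -1:]
    frac = cs / np.maximum(tot, _EPS)
    idx = np.argmax(frac >= 0.5, axis=1)
    return (idx + 1) / X.shape[1]


def _trend_terms(X, fs):
    t = np.arange(X.shape[1]) / fs
    tc = t - t.mean()
    denom = np.sum(tc * tc)
    slope = (X - X.mean(axis=1, keepdims=True)) @ tc / max(denom, _EPS)
    intercept = X.mean(axis=1) - slope * t.mean()
    return slope, intercept


def _f_linear_trend_slope(X, fs):
    return _trend_terms(X, fs)[0]


def _f_linear_trend_intercept(X, fs):
    return _trend_terms(X, fs)[1]


def _f_abs_sum_changes(X, fs):
    return np.sum(np.abs(np.diff(X, axis=1)), axis=1)


def _f_mean_second_derivative(X, fs):
    if X.shape[1] < 3:
        return np.zeros(X.shape[0])
    return np.mean((X[:, 2:] - 2 * X[:, 1:-1] + X[:, :-2]) / 2.0, axis=1)


def _f_time_reversal_asymmetry_1(X, fs):
    if X.shape[1] < 3:
        return np.zeros(X.shape[0])
    x0, x1, x2 = X[:, :-2], X[:, 1:-1], X[:, 2:]
    return np.mean(x2 * x2 * x1 - x1 * x0 * x0, axis=1)


# ---------------------------------------------------------------------------
# frequency-domain features (single full-window periodogram, DC excluded)
# ---------------------------------------------------------------------------

def _psd(X, fs):
    def build():
        F = np.fft.rfft(X, axis=1)
        p = (F.real ** 2 + F.imag ** 2) / (X.shape[1] * fs)
        p[:, 0] = 0.0  # discard DC: level is a time-domain property
        f = np.fft.rfftfreq(X.shape[1], d=1.0 / fs)
        return (f, p)
    return _memo(("psd", fs), X, build)


def _f_dominant_frequency(X, fs):
    f, p = _psd(X, fs)
    return f[np.argmax(p, axis=1)]


def _f_spectral_centroid(X, fs):
    f, p = _psd(X, fs)
    tot = p.sum(axis=1)
    return np.where(tot > _EPS, (p @ f) / np.maximum(tot, _EPS), 0.0)


def _f_spectral_spread(X, fs):
    f, p = _psd(X, fs)
    tot = p.sum(axis=1)
    c = np.where(tot > _EPS, (p @ f) / np.maximum(tot, _EPS), 0.0)
    var = np.einsum("ij,ij->i", p, (f[None, :] - c[:, None]) ** 2) / np.maximum(tot, _EPS)
    return np.where(tot > _EPS, np.sqrt(np.maximum(var, 0.0)), 0.0)


def _f_spectral_entropy(X, fs):
    f, p = _psd(X, fs)
    tot = p.sum(axis=1, keepdims=True)
    pn = p / np.maximum(tot, _EPS)
    h = -np.sum(np.where(pn > 0, pn * np.log(np.maximum(pn, _EPS)), 0.0), axis=1)
    nbins = p.shape[1] - 1
    out = h / np.log(max(nbins, 2))
    return np.where(tot[:, 0] > _EPS, out, 0.0)


def _f_spectral_flatness(X, fs):
    f, p = _psd(X, fs)
    q = p[:, 1:]  # DC already zeroed; skip the slot entirely
    gm = np.exp(np.mean(np.log(q + _EPS), axis=1))
    am = np.mean(q, axis=1)
    return np.where(am > _EPS, gm / np.maximum(am, _EPS), 0.0)


def _cum_freq_at(frac):
    def f(X, fs):
        fr, p = _psd(X, fs)
        tot = p.sum(axis=1, keepdims=True)
        cs = np.cumsum(p, axis=1) / np.maximum(tot, _EPS)
        idx = np.argmax(cs >= frac, axis=1)
        return np.where(tot[:, 0] > _EPS, fr[idx], 0.0)
    return f


def _f_total_power(X, fs):
    return _psd(X, fs)[1].sum(axis=1)


def _f_peak_power(X, fs):
    return _psd(X, fs)[1].max(axis=1)


def _band_energy(lo, hi):
    def f(X, fs):
        fr, p = _psd(X, fs)
        sel = (fr >= lo) & (fr < hi)
        return p[:, sel].sum(axis=1) if sel.any() else np.zeros(X.shape[0])
    return f


def _f_low_high_power_ratio(X, fs):
    fr, p = _psd(X, fs)
    low = p[:, fr <= 2.5].sum(axis=1)
    high = p[:, fr > 2.5].sum(axis=1)
    return low / np.maximum(high, _EPS)


FEATURE_FUNCS = {
    # time domain
    "mean": _f_mean,
    "std": _f_std,
    "variance": _f_variance,
    "minimum": _f_minimum,
    "maximum": _f_maximum,
    "median": _f_median,
    "range": _f_range,
    "rms": _f_rms,
    "abs_energy": _f_abs_energy,
    "skewness": _f_skewness,
    "kurtosis": _f_kurtosis,
    "zero_crossings": _f_zero_crossings,
    "mean_abs_change": _f_mean_abs_change,
    "mean_change": _f_mean_change,
    "abs_max": _f_abs_max,
    "quantile_05": _quantile(0.05),
    "quantile_10": _quantile(0.10),
    "quantile_25": _quantile(0.25),
    "quantile_75": _quantile(0.75),
    "quantile_90": _quantile(0.90),
    "quantile_95": _quantile(0.95),
    "iqr": _f_iqr,
    "autocorr_lag_1": _autocorr(1),
    "autocorr_lag_2": _autocorr(2),
    "autocorr_lag_3": _autocorr(3),
    "autocorr_lag_4": _autocorr(4),
    "autocorr_lag_5": _autocorr(5),
    "autocorr_lag_6": _autocorr(6),
    "autocorr_lag_7": _autocorr(7),
    "autocorr_lag_8": _autocorr(8),
    "autocorr_lag_9": _autocorr(9),
    "autocorr_lag_10": _autocorr(10),
    "count_above_mean": _f_count_above_mean,
    "count_below_mean": _f_count_below_mean,
    "sum_abs": _f_sum_abs,
    "sum_values": _f_sum_values,
    "mean_abs_dev": _f_mean_abs_dev,
    "median_abs_dev": _f_median_abs_dev,
    "cid_ce": _f_cid_ce,
    "number_peaks_3": _f_number_peaks_3,
    "binned_entropy_10": _f_binned_entropy_10,
    "first_location_of_max": _f_first_location_of_max,
    "last_location_of_max": _f_last_location_of_max,
    "first_location_of_min": _f_first_location_of_min,
    "last_location_of_min": _f_last_location_of_min,
    "ratio_beyond_1_sigma": _ratio_beyond_sigma(1),
    "ratio_beyond_2_sigma": _ratio_beyond_sigma(2),
    "ratio_beyond_3_sigma": _ratio_beyond_sigma(3),
    "longest_strike_above_mean": _f_longest_strike_above_mean,
    "longest_strike_below_mean": _f_longest_strike_below_mean,
    "variation_coefficient": _f_variation_coefficient,
    "energy_ratio_first_half": _f_energy_ratio_first_half,
    "index_mass_quantile_50": _f_index_mass_quantile_50,
    "linear_trend_slope": _f_linear_trend_slope,
    "linear_trend_intercept": _f_linear_trend_intercept,
    "abs_sum_changes": _f_abs_sum_changes,
    "mean_second_derivative": _f_mean_second_derivative,
    "time_reversal_asymmetry_1": _f_time_reversal_asymmetry_1,
    # frequency domain
    "dominant_frequency": _f_dominant_frequency,
    "spectral_centroid": _f_spectral_centroid,
    "spectral_spread": _f_spectral_spread,
    "spectral_entropy": _f_spectral_entropy,
    "spectral_flatness": _f_spectral_flatness,
    "median_frequency": _cum_freq_at(0.5),
    "spectral_rolloff_85": _cum_freq_at(0.85),
    "total_power": _f_total_power,
    "peak_power": _f_peak_power,
    "band_energy_0.3_1": _band_energy(0.3, 1.0),
    "band_energy_1_3": _band_energy(1.0, 3.0),
    "band_energy_3_5": _band_energy(3.0, 5.0),
    "band_energy_5_8": _band_energy(5.0, 8.0),
    "band_energy_8_15": _band_energy(8.0, 15.0),
    "low_high_power_ratio": _f_low_high_power_ratio,
}


# ---------------------------------------------------------------------------
# catalogues
# ---------------------------------------------------------------------------

@dataclass
class FeatureCatalogue:
    """Ordered feature list defining a feature-table layout.

    ``entries`` rows are ``(name, domain, inputs)`` where ``inputs`` is the
    tuple of series the feature applies to.  For the hourly catalogue the
    inputs are the five raw signals (identical for every entry); for the HAR
    catalogue they are the seven derived series.
    """

    scope: str  # "hourly" | "har"
    entries: list[tuple[str, str, tuple[str, ...]]]

    @property
    def n_expanded(self) -> int:
        return sum(len(inputs) for _, _, inputs in self.entries)

    def column_names(self) -> list[str]:
        cols: list[str] = []
        if self.scope == "hourly":
            # grouped by signal so each signal's 73-block is contiguous
            for sig in HOURLY_SIGNALS:
                cols.extend(f"{sig}__{name}" for name, _, _ in self.entries)
        else:
            for name, _, inputs in self.entries:
                cols.extend(f"{series}__{name}" for series in inputs)
        return cols

    def validate(self) -> None:
        names = [n for n, _, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in catalogue")
        unknown = [n for n in names if n not in FEATURE_FUNCS]
        if unknown:
            raise ValueError(f"unknown features: {unknown}")
        if self.scope == "hourly":
            if len(self.entries) != N_HOURLY_FEATURES:
                raise ValueError(
                    f"hourly catalogue must have {N_HOURLY_FEATURES} entries, "
                    f"got {len(self.entries)}"
                )
        elif self.scope == "har":
            if self.n_expanded != N_HAR_FEATURES:
                raise ValueError(
                    f"har catalogue must expand to {N_HAR_FEATURES} features, "
                    f"got {self.n_expanded}"
                )
        else:
            raise ValueError(f"unknown scope {self.scope!r}")


def load_catalogue(scope: str, path: str | Path | None = None) -> FeatureCatalogue:
    """Load the packaged catalogue for ``scope``, or a user-supplied CSV."""
    if path is None:
        ref = resources.files("wearcontext").joinpath(f"catalogues/{scope}.csv")
        with resources.as_file(ref) as fp:
            df = pd.read_csv(fp)
    else:
        df = pd.read_csv(path)
    entries = []
    for _, row in df.iterrows():
        if scope == "hourly":
            inputs = HOURLY_SIGNALS
        else:
            inputs = tuple(str(row["inputs"]).split(";"))
        entries.append((str(row["name"]), str(row["domain"]), tuple(inputs)))
    cat = FeatureCatalogue(scope, entries)
    cat.validate()
    return cat


# ---------------------------------------------------------------------------
# GSR decomposition and HAR preprocessing
# ---------------------------------------------------------------------------

#: tonic estimator span: centered moving average over 4 s at 4 Hz
TONIC_SPAN_SAMPLES = 17


def decompose_gsr(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-normalize GSR and split into (tonic, phasic).

    The tonic (slow baseline) component is a centered moving average of the
    normalized signal; the phasic (event-driven) component is the residual,
    so ``tonic + phasic`` reconstructs the normalized signal exactly.  A
    constant input z-normalizes to zeros (zero sd convention).
    """
    X = np.atleast_2d(np.asarray(values, dtype=np.float64))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    z = np.where(sd > _EPS, (X - mu) / np.maximum(sd, _EPS), 0.0)
    tonic = uniform_filter1d(z, size=TONIC_SPAN_SAMPLES, axis=1, mode="nearest")
    phasic = z - tonic
    if np.asarray(values).ndim == 1:
        return tonic[0], phasic[0]
    return tonic, phasic


def preprocess_har_accel(window: Window) -> dict[str, np.ndarray]:
    """Band-passed accelerometer series for one HAR window.

    The Euclidean norm is computed from the raw axes *before* filtering;
    all four series then pass through the order-4 Butterworth band-pass
    (0.3–15 Hz) at 32 Hz.
    """
    x, y, z = (window.samples[c] for c in ACCEL_CHANNELS)
    norm = euclidean_norm(x, y, z)
    out = {}
    for name, series in zip(("accel_x", "accel_y", "accel_z", "accel_norm"), (x, y, z, norm)):
        out[name] = bandpass(series, 32.0, order=4, low=0.3, high=15.0)
    return out


def _fill_nans(X: np.ndarray) -> np.ndarray:
    """Linear interpolation of NaN stretches (usable windows only)."""
    if not np.isnan(X).any():
        return X
    X = X.copy()
    idx = np.arange(X.shape[1])
    for row in X:
        bad = np.isnan(row)
        if bad.any():
            row[bad] = np.interp(idx[bad], idx[~bad], row[~bad])
    return X


# ---------------------------------------------------------------------------
# batched extraction
# ---------------------------------------------------------------------------

def _apply_catalogue(series: np.ndarray, fs: float, names: list[str]) -> np.ndarray:
    series = _fill_nans(series)
    out = np.column_stack([FEATURE_FUNCS[name](series, fs) for name in names])
    _CACHE.clear()
    return out


def extract_hourly_features_batch(
    windows: list[Window], catalogue: FeatureCatalogue
) -> pd.DataFrame:
    """Hourly physiological feature table: one row per window, 365 columns
    plus ``hour_start`` and ``usable``.  Unusable hours (any channel below
    the 80 % completeness rule) keep NaN features and ``usable=False``."""
    if catalogue.scope != "hourly":
        raise ValueError("need an hourly-scope catalogue")
    names = [n for n, _, _ in catalogue.entries]
    cols = catalogue.column_names()
    n = len(windows)
    out = np.full((n, len(cols)), np.nan)
    usable = np.array([w.usable() for w in windows])
    idx_ok = np.flatnonzero(usable)
    if len(idx_ok):
        for s_i, sig in enumerate(HOURLY_SIGNALS):
            fs = 32.0 if sig.startswith("accel") else 4.0
            stack = np.stack([windows[i].samples[sig] for i in idx_ok])
            block = _apply_catalogue(stack, fs, names)
            out[idx_ok, s_i * len(names):(s_i + 1) * len(names)] = block
    df = pd.DataFrame(out, columns=cols)
    df.insert(0, "hour_start", [w.start for w in windows])
    df["usable"] = usable
    return df


def extract_hourly_features(window: Window, catalogue: FeatureCatalogue) -> pd.Series:
    """Single-hour convenience wrapper; see the batch variant."""
    if abs(window.duration - 3600.0) > 1e-9:
        raise ValueError("hourly features need a 3600 s window")
    return extract_hourly_features_batch([window], catalogue).iloc[0]


def _har_series_batch(windows: list[Window]) -> dict[str, np.ndarray]:
    """Stack and preprocess the seven derived HAR series for a window batch."""
    acc = {c: np.stack([_fill_nans(np.atleast_2d(w.samples[c]))[0] for w in windows])
           for c in ACCEL_CHANNELS}
    norm = np.sqrt(acc["accel_x"] ** 2 + acc["accel_y"] ** 2 + acc["accel_z"] ** 2)
    series: dict[str, np.ndarray] = {}
    from scipy import signal as _sig
    sos = _sig.butter(4, [0.3, 15.0], btype="bandpass", fs=32.0, output="sos")
    for name, raw in (("accel_x", acc["accel_x"]), ("accel_y", acc["accel_y"]),
                      ("accel_z", acc["accel_z"]), ("accel_norm", norm)):
        series[name] = _sig.sosfiltfilt(sos, raw, axis=1)
    gsr = np.stack([_fill_nans(np.atleast_2d(w.samples["gsr"]))[0] for w in windows])
    tonic, phasic = decompose_gsr(gsr)
    series["gsr_tonic"] = tonic
    series["gsr_phasic"] = phasic
    series["skin_temp"] = np.stack(
        [_fill_nans(np.atleast_2d(w.samples["skin_temp"]))[0] for w in windows]
    )
    return series


def extract_har_features_batch(
    windows: list[Window], catalogue: FeatureCatalogue
) -> pd.DataFrame:
    """HAR feature table: one row per usable 15 s window, 228 columns plus
    ``window_start``.  Unusable windows are skipped (not returned)."""
    if catalogue.scope != "har":
        raise ValueError("need a har-scope catalogue")
    keep = [w for w in windows if w.usable()]
    if not keep:
        return pd.DataFrame(columns=["window_start"] + catalogue.column_names())
    series = _har_series_batch(keep)
    blocks = []
    for name, _, inputs in catalogue.entries:
        fn = FEATURE_FUNCS[name]
        for s in inputs:
            blocks.append(fn(series[s], HAR_SERIES_RATES[s]))
    out = np.column_stack(blocks)
    _CACHE.clear()
    df = pd.DataFrame(out, columns=catalogue.column_names())
    df.insert(0, "window_start", [w.start for w in keep])
    return df


def extract_har_features(window: Window, catalogue: FeatureCatalogue) -> pd.Series:
    """Single 15 s window convenience wrapper; see the batch variant."""
    if abs(window.duration - 15.0) > 1e-9:
        raise ValueError("HAR features need a 15 s window")
    df = extract_har_features_batch([window], catalogue)
    if df.empty:
        raise ValueError("window unusable (below completeness threshold)")
    return df.iloc[0]
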