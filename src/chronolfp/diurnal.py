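"""Diurnal structure of chronic band-power streams.

The central quantity is the **variance explained by time of day**.  A
nonparametric time-of-day model is fitted by dividing the 24-h clock into
30-minute bins, taking the mean value in each bin, and linearly
interpolating between bin centres (circularly across midnight by default).
Subtracting the fitted value at each sample's clock time removes the
influence of time of day; the variance explained is

    VE = (var_total − var_residual) / var_total .

Significance is assessed with a **temporal shuffling test**: each surrogate
applies an independent uniform circular shift (a whole number of sample
intervals, 0–24 h) to every civil day's samples, destroying clock-time
alignment across days while preserving each day's internal structure.  The
empirical p-value uses the add-one rule, p = (1 + #{VE_null ≥ VE_obs}) /
(1 + n_shuffles), so the attainable floor with 1000 surrogates is 1/1001.

24-h periodicity itself is read off a Welch periodogram of the (regularly
resampled) stream, with 4-day Hann windows so a 24-h period falls exactly
on a frequency bin.

The module also exposes display summaries (the binned diurnal profile and
the day × clock-bin matrix) and a statsmodels-flavoured
``TimeOfDayModel``/``TimeOfDayResults`` pair wrapping the same operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import AnalysisError, ValidationError
from .series import BandPowerSeries, format_clock, parse_clock

__all__ = [
    "TimeOfDayFit", "VarianceExplained", "ShuffleTestResult",
    "PeriodogramResult", "DiurnalProfile", "DayMatrix",
    "fit_time_of_day", "variance_explained", "temporal_shuffle_test",
    "periodogram", "windowed_variance_explained", "diurnal_profile",
    "day_matrix", "TimeOfDayModel", "TimeOfDayResults",
]

_MIN_PER_DAY = 24 * 60.0


def _check_bin_width(bin_minutes: float) -> int:
    nbins = _MIN_PER_DAY / bin_minutes
    if bin_minutes <= 0 or abs(nbins - round(nbins)) > 1e-9:
        raise ValidationError(
            f"bin width {bin_minutes} min must divide 24 h")
    return int(round(nbins))


def _fill_circular(values: np.ndarray) -> np.ndarray:
    """Fill NaN entries of a circular array by linear interpolation between
    the nearest finite neighbours (used for empty clock bins)."""
    out = values.copy()
    n = out.size
    good = np.flatnonzero(np.isfinite(out))
    if good.size == 0:
        raise AnalysisError("no non-empty clock bins")
    if good.size == n:
        return out
    idx = np.arange(n)
    # unwrap onto an extended axis so np.interp handles the wrap
    xp = np.concatenate([good - n, good, good + n]).astype(float)
    fp = np.tile(out[good], 3)
    out[~np.isfinite(out)] = np.interp(idx[~np.isfinite(out)].astype(float),
                                       xp, fp)
    return out


# ---------------------------------------------------------------------- fit

@dataclass
class TimeOfDayFit:
    """Clock-time fit: per-bin means with linear interpolation between
    bin centres (circular across midnight when ``wrap``)."""

    bin_minutes: float
    bin_means: np.ndarray
    counts: np.ndarray
    wrap: bool = True

    @property
    def bin_centers(self) -> np.ndarray:
        n = self.bin_means.size
        return (np.arange(n) + 0.5) * self.bin_minutes

    def predict(self, clock_minutes) -> np.ndarray:
        """Fit value at arbitrary clock times (minutes of day)."""
        m = np.asarray(clock_minutes, dtype=float) % _MIN_PER_DAY
        means = self.bin_means
        n = means.size
        if self.wrap:
            u = (m - self.bin_minutes / 2.0) / self.bin_minutes
            b0 = np.floor(u).astype(int) % n
            frac = u - np.floor(u)
            return (1 - frac) * means[b0] + frac * means[(b0 + 1) % n]
        return np.interp(m, self.bin_centers, means)


def _bin_means(minutes: np.ndarray, values: np.ndarray, bin_minutes: float,
               ) -> tuple[np.ndarray, np.ndarray]:
    nbins = _check_bin_width(bin_minutes)
    bins = np.minimum((minutes / bin_minutes).astype(int), nbins - 1)
    counts = np.bincount(bins, minlength=nbins)
    sums = np.bincount(bins, weights=values, minlength=nbins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def fit_time_of_day(series: BandPowerSeries, bin_minutes: float = 30.0,
                    wrap: bool = True) -> TimeOfDayFit:
    """Fit the binned-mean time-of-day model to a series.

    Empty bins are interpolated across from their neighbours; at least two
    non-empty bins are required.
    """
    if len(series) == 0:
        raise AnalysisError("cannot fit an empty series")
    means, counts = _bin_means(series.clock_minutes, series.values,
                               bin_minutes)
    if (counts > 0).sum() < 2:
        raise AnalysisError("time-of-day fit needs samples in >= 2 clock bins")
    means = _fill_circular(means)
    return TimeOfDayFit(bin_minutes, means, counts, wrap=wrap)


# ------------------------------------------------------------------ variance

@dataclass
class VarianceExplained:
    """Fraction of variance removed by the time-of-day fit."""

    ve: float
    var_total: float
    var_residual: float
    n: int = 0


def variance_explained(series: BandPowerSeries,
                       fit: TimeOfDayFit | None = None,
                       bin_minutes: float = 30.0) -> VarianceExplained:
    """VE = (var_total − var_residual)/var_total after subtracting the fit
    value at each sample's clock time.

    May be slightly negative when the fit generalises poorly (e.g. a fit
    from unrelated data); reported as-is, never clamped.
    """
    if fit is None:
        fit = fit_time_of_day(series, bin_minutes)
    values = series.values
    var_total = float(np.var(values))
    if not var_total > 0:
        raise AnalysisError("zero total variance; VE undefined")
    resid = values - fit.predict(series.clock_minutes)
    var_resid = float(np.var(resid))
    return VarianceExplained((var_total - var_resid) / var_total,
                             var_total, var_resid, n=len(series))


# -------------------------------------------------------------- shuffle test

@dataclass
class ShuffleTestResult:
    """Day-shift permutation test of the variance explained by time of day."""

    observed_ve: float
    null_ve: np.ndarray
    p_value: float
    n_shuffles: int
    seed: int | None = None

    def __post_init__(self):
        if len(self.null_ve) != self.n_shuffles:
            raise ValidationError("null distribution length != n_shuffles")


def _ve_for_clock_matrix(minutes: np.ndarray, values: np.ndarray,
                         bin_minutes: float, var_total: float) -> np.ndarray:
    """VE for each row of a (surrogates × samples) clock-minute matrix.

    Vectorised: per-row bin means via scatter-add, then circular linear
    interpolation at each sample's (shifted) clock time.
    """
    nbins = _check_bin_width(bin_minutes)
    S, n = minutes.shape
    bins = np.minimum((minutes / bin_minutes).astype(int), nbins - 1)
    flat = (bins + nbins * np.arange(S)[:, None]).ravel()
    counts = np.bincount(flat, minlength=S * nbins).reshape(S, nbins)
    sums = np.bincount(flat, weights=np.broadcast_to(values, (S, n)).ravel(),
                       minlength=S * nbins).reshape(S, nbins)
    empty = counts == 0
    means = sums / np.maximum(counts, 1.0)
    if empty.any():
        # rare with multi-day data; fall back to the overall mean there
        means[empty] = values.mean()
    u = (minutes - bin_minutes / 2.0) / bin_minutes
    b0 = np.floor(u).astype(int) % nbins
    frac = u - np.floor(u)
    fit = ((1 - frac) * np.take_along_axis(means, b0, axis=1)
           + frac * np.take_along_axis(means, (b0 + 1) % nbins, axis=1))
    resid = values[None, :] - fit
    return (var_total - resid.var(axis=1)) / var_total


def temporal_shuffle_test(series: BandPowerSeries, n_shuffles: int = 1000,
                          seed: int | None = None, bin_minutes: float = 30.0,
                          ) -> ShuffleTestResult:
    """Permutation test: circularly shift each civil day by an independent
    uniform whole-sample offset (0–24 h) and recompute VE.

    p = (1 + #{null VE ≥ observed VE}) / (1 + n_shuffles).
    """
    codes, days = series.day_codes()
    if len(days) < 2:
        raise AnalysisError("shuffle test needs >= 2 days of data")
    interval = series.sample_interval.total_seconds() / 60.0
    slots = _MIN_PER_DAY / interval
    if abs(slots - round(slots)) > 1e-9:
        raise AnalysisError("sample interval must divide 24 h")
    slots = int(round(slots))
    rng = np.random.default_rng(seed)
    minutes = series.clock_minutes
    values = series.values
    var_total = float(np.var(values))
    if not var_total > 0:
        raise AnalysisError("zero total variance; shuffle test undefined")
    observed = variance_explained(series, bin_minutes=bin_minutes).ve
    null = np.empty(n_shuffles)
    # chunk the surrogate matrix to bound memory at ~10**7 elements
    chunk = max(1, int(10_000_000 // max(len(series), 1)))
    done = 0
    while done < n_shuffles:
        k = min(chunk, n_shuffles - done)
        offsets = rng.integers(0, slots, size=(k, len(days)))
        shift = offsets[:, codes] * interval
        shifted = (minutes[None, :] + shift) % _MIN_PER_DAY
        null[done:done + k] = _ve_for_clock_matrix(
            shifted, values, bin_minutes, var_total)
        done += k
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_shuffles)
    return ShuffleTestResult(observed, null, p, n_shuffles, seed)


# --------------------------------------------------------------- periodogram

@dataclass
class PeriodogramResult:
    """Welch periodicity estimate over periods (hours)."""

    periods_h: np.ndarray
    power: np.ndarray
    dominant_period_h: float


def periodogram(series: BandPowerSeries, segment_days: float = 4.0,
                max_gap: str | pd.Timedelta = "2h",
                min_period_h: float = 2.0) -> PeriodogramResult:
    """Welch periodogram of the stream, reported over periods in hours.

    The series is placed on its regular nominal grid; gaps of at most
    ``max_gap`` are linearly interpolated, longer gaps split the record into
    chunks whose Welch estimates are averaged (weighted by chunk length).
    Hann windows of ``segment_days`` (default 4, placing 24 h exactly on a
    frequency bin) with 50% overlap; power is normalised to unit total.
    The dominant period is searched over [``min_period_h``, half the record].
    """
    if len(series) < 2:
        raise AnalysisError("periodogram needs a longer record")
    interval = series.sample_interval
    span = series.timestamps[-1] - series.timestamps[0]
    if span < pd.Timedelta(days=2):
        raise AnalysisError("periodogram needs >= 2 days of data")
    grid = pd.date_range(series.timestamps[0], series.timestamps[-1],
                         freq=interval)
    s = pd.Series(series.values, index=series.timestamps)
    s = s.reindex(grid.union(series.timestamps)).interpolate(
        method="time", limit_area="inside").reindex(grid)
    max_gap = pd.Timedelta(max_gap)
    # re-blank samples interpolated across gaps longer than max_gap
    obs = pd.Series(1.0, index=series.timestamps).reindex(grid)
    filled = obs.isna()
    if filled.any():
        gap_id = (~filled).cumsum()
        gap_len = filled.groupby(gap_id).transform("sum")
        too_long = filled & (gap_len * interval > max_gap)
        s[too_long.to_numpy()] = np.nan
    fs_per_day = pd.Timedelta(days=1) / interval
    nperseg = int(round(segment_days * fs_per_day))
    values = s.to_numpy()
    chunks = []
    for chunk in np.split(values, np.flatnonzero(np.diff(np.isnan(values))) + 1):
        if not np.isnan(chunk[0]) and chunk.size >= 2:
            chunks.append(chunk)
    if not chunks:
        raise AnalysisError("no contiguous data after gap handling")
    longest = max(c.size for c in chunks)
    nperseg = min(nperseg, longest)
    psd_sum, weight = None, 0.0
    for chunk in chunks:
        if chunk.size < nperseg:
            continue
        freqs, psd = signal.welch(chunk, fs=float(fs_per_day), window="hann",
                                  nperseg=nperseg, noverlap=nperseg // 2,
                                  detrend="constant")
        w = chunk.size
        psd_sum = psd * w if psd_sum is None else psd_sum + psd * w
        weight += w
    psd = psd_sum / weight
    keep = freqs > 0
    periods_h = 24.0 / freqs[keep]
    power = psd[keep]
    total_h = span.total_seconds() / 3600.0
    search = (periods_h >= min_period_h) & (periods_h <= total_h / 2.0)
    if not search.any():
        raise AnalysisError("no periods in the searchable range")
    if power.sum() > 0:
        power = power / power.sum()
    dominant = float(periods_h[search][np.argmax(power[search])])
    return PeriodogramResult(periods_h, power, dominant)


# ------------------------------------------------------------ windowed VE

def windowed_variance_explained(series: BandPowerSeries, window,
                                bin_minutes: float = 30.0,
                                ) -> VarianceExplained:
    """VE computed from in-window samples and in-window clock bins only.

    ``window`` is a (start, end) pair of clock times; start == end denotes
    the full day (then this reduces exactly to :func:`variance_explained`).
    Windows may cross midnight; the fit within a partial window is linear
    (non-circular) over the window's bin centres.
    """
    start = parse_clock(window[0])
    end = parse_clock(window[1])
    if start == end:
        return variance_explained(series, bin_minutes=bin_minutes)
    minutes = series.clock_minutes
    # rotate clock so the window starts at 0; handles midnight crossing
    rel = (minutes - start) % _MIN_PER_DAY
    length = (end - start) % _MIN_PER_DAY
    inside = rel < length
    if not inside.any():
        raise AnalysisError("no samples inside the clock window")
    sub_minutes = rel[inside]
    sub_values = series.values[inside]
    var_total = float(np.var(sub_values))
    if not var_total > 0:
        raise AnalysisError("zero variance inside the window")
    means, counts = _bin_means(sub_minutes, sub_values, bin_minutes)
    nbins_window = int(np.ceil(length / bin_minutes))
    means = means[:nbins_window]
    if np.isfinite(means).sum() < 2:
        raise AnalysisError("windowed fit needs >= 2 non-empty bins")
    centers = (np.arange(nbins_window) + 0.5) * bin_minutes
    ok = np.isfinite(means)
    fit_vals = np.interp(sub_minutes, centers[ok], means[ok])
    var_resid = float(np.var(sub_values - fit_vals))
    return VarianceExplained((var_total - var_resid) / var_total,
                             var_total, var_resid, n=int(inside.sum()))


# ------------------------------------------------------------------ profiles

@dataclass
class DiurnalProfile:
    """Binned clock-time profile for display (rose plots etc.)."""

    bin_minutes: float
    bin_centers_min: np.ndarray
    stat_per_bin: np.ndarray
    count_per_bin: np.ndarray
    statistic: str = "median"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "clock": [format_clock(c) for c in self.bin_centers_min],
            self.statistic: self.stat_per_bin,
            "n": self.count_per_bin,
        })


def diurnal_profile(series: BandPowerSeries, bin_minutes: float = 30.0,
                    statistic: str = "median",
                    per_day_first: bool = False) -> DiurnalProfile:
    """Central statistic of (detrended) values per clock bin.

    With ``per_day_first`` the two-stage variant is used: the statistic is
    taken per day per bin first, then across days.  Empty bins are NaN.
    """
    nbins = _check_bin_width(bin_minutes)
    if statistic not in ("median", "mean"):
        raise ValidationError("statistic must be median or mean")
    bins = np.minimum((series.clock_minutes / bin_minutes).astype(int),
                      nbins - 1)
    df = pd.DataFrame({"bin": bins, "value": series.values})
    agg = statistic
    if per_day_first:
        codes, _ = series.day_codes()
        df["day"] = codes
        per_day = df.groupby(["day", "bin"])["value"].agg(agg)
        stat = per_day.groupby("bin").agg(agg)
    else:
        stat = df.groupby("bin")["value"].agg(agg)
    out = np.full(nbins, np.nan)
    out[stat.index.to_numpy()] = stat.to_numpy()
    counts = np.bincount(bins, minlength=nbins)
    centers = (np.arange(nbins) + 0.5) * bin_minutes
    return DiurnalProfile(bin_minutes, centers, out, counts, statistic)


@dataclass
class DayMatrix:
    """Days × clock-bins matrix of (detrended) values; NaN marks missing."""

    matrix: np.ndarray
    day_labels: pd.DatetimeIndex
    bin_centers_min: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=pd.Index([d.date() for d in self.day_labels], name="date"),
            columns=[format_clock(c) for c in self.bin_centers_min])


def day_matrix(series: BandPowerSeries, bin_minutes: float = 30.0,
               statistic: str = "median") -> DayMatrix:
    """Per-day, per-clock-bin central statistic (heat-map source)."""
    nbins = _check_bin_width(bin_minutes)
    codes, days = series.day_codes()
    bins = np.minimum((series.clock_minutes / bin_minutes).astype(int),
                      nbins - 1)
    df = pd.DataFrame({"day": codes, "bin": bins, "value": series.values})
    stat = df.groupby(["day", "bin"])["value"].agg(statistic)
    mat = np.full((len(days), nbins), np.nan)
    ii = stat.index.get_level_values(0).to_numpy()
    jj = stat.index.get_level_values(1).to_numpy()
    mat[ii, jj] = stat.to_numpy()
    centers = (np.arange(nbins) + 0.5) * bin_minutes
    return DayMatrix(mat, pd.DatetimeIndex(days), centers)


# ----------------------------------------------------- model/results objects

class TimeOfDayModel:
    """Statsmodels-style front end to the time-of-day analysis.

    Parameters
    ----------
    series : BandPowerSeries
        Typically the outlier-cleaned, daily-detrended stream.
    bin_minutes : float
        Clock-bin width of the fit (default 30).
    wrap : bool
        Interpolate circularly across midnight (default True).
    """

    def __init__(self, series: BandPowerSeries, bin_minutes: float = 30.0,
                 wrap: bool = True):
        self.series = series
        self.bin_minutes = float(bin_minutes)
        self.wrap = wrap

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "timestamp",
                       value_col: str = "value", **kwargs) -> "TimeOfDayModel":
        series = BandPowerSeries(pd.DatetimeIndex(df[time_col]),
                                 df[value_col].to_numpy(dtype=float))
        return cls(series, **kwargs)

    def fit(self) -> "TimeOfDayResults":
        tod = fit_time_of_day(self.series, self.bin_minutes, self.wrap)
        ve = variance_explained(self.series, tod)
        return TimeOfDayResults(self, tod, ve)


@dataclass
class TimeOfDayResults:
    """Fitted time-of-day model with its variance decomposition."""

    model: TimeOfDayModel
    fit: TimeOfDayFit
    ve: VarianceExplained
    shuffle: ShuffleTestResult | None = field(default=None, repr=False)

    def predict(self, clock) -> np.ndarray:
        m = [parse_clock(c) for c in np.atleast_1d(clock)]
        return self.fit.predict(np.asarray(m))

    def shuffle_test(self, n_shuffles: int = 1000,
                     seed: int | None = None) -> ShuffleTestResult:
        self.shuffle = temporal_shuffle_test(
            self.model.series, n_shuffles, seed, self.model.bin_minutes)
        return self.shuffle

    def periodogram(self, **kwargs) -> PeriodogramResult:
        return periodogram(self.model.series, **kwargs)

    def summary(self) -> str:
        s = self.model.series
        lines = [
            "Time-of-day model".center(56),
            "=" * 56,
            f"{'No. samples:':<24}{len(s)}",
            f"{'No. days:':<24}{len(s.day_codes()[1])}",
            f"{'Bin width (min):':<24}{self.model.bin_minutes:g}",
            f"{'Circular fit:':<24}{self.model.wrap}",
            "-" * 56,
            f"{'Variance explained:':<24}{self.ve.ve:.3f}",
            f"{'Total variance:':<24}{self.ve.var_total:.4g}",
            f"{'Residual variance:':<24}{self.ve.var_residual:.4g}",
        ]
        if self.shuffle is not None:
            lines += [
                f"{'Shuffle p-value:':<24}{self.shuffle.p_value:.4g}"
                f"  ({self.shuffle.n_shuffles} surrogates)",
            ]
        peak_bin = int(np.argmax(self.fit.bin_means))
        trough_bin = int(np.argmin(self.fit.bin_means))
        lines += [
            f"{'Profile peak:':<24}"
            f"{format_clock(self.fit.bin_centers[peak_bin])}"
            f"  ({self.fit.bin_means[peak_bin]:.3f})",
            f"{'Profile trough:':<24}"
            f"{format_clock(self.fit.bin_centers[trough_bin])}"
            f"  ({self.fit.bin_means[trough_bin]:.3f})",
            "=" * 56,
        ]
        return "\n".join(lines)
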