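"""Sleep/wake epoch analyses of chronic band-power streams.

Relates the 10-minute band-power stream to the patient's sleep schedule:
diary-based in-bed masks, day-by-day alignment to a daily event (waking, or
the first scheduled medication intake as a proxy), sleep/wake power
contrast, and day/night value distributions compared against a single
in-clinic measurement.  Default clock windows follow the convention of a
night window dominated by sleep (00:00–06:00) and a day window dominated by
waking (08:00–20:00).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

from .exceptions import AnalysisError, ValidationError
from .series import BandPowerSeries, parse_clock

__all__ = ["SleepDiary", "AlignedTraces", "DayNightSummary",
           "in_bed_mask", "align_to_daily_event", "sleep_wake_contrast",
           "day_night_summary", "DAY_WINDOW", "NIGHT_WINDOW"]

DAY_WINDOW = ("08:00", "20:00")
NIGHT_WINDOW = ("00:00", "06:00")

_MIN_PER_DAY = 24 * 60.0


class SleepDiary:
    """Per-day (bed_time, rise_time) intervals in local civil time.

    Intervals may cross midnight; each must have positive duration.  The
    diary date of an entry is the civil date of its bed time.
    """

    def __init__(self, entries):
        intervals = []
        for bed, rise in entries:
            bed, rise = pd.Timestamp(bed), pd.Timestamp(rise)
            if not rise > bed:
                raise ValidationError(
                    f"diary interval {bed} .. {rise} has non-positive duration")
            intervals.append((bed, rise))
        intervals.sort(key=lambda iv: iv[0])
        self.intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = intervals

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def dates(self) -> list:
        return [bed.date() for bed, _ in self.intervals]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "date": [bed.date().isoformat() for bed, _ in self.intervals],
            "bed_time": [bed.strftime("%H:%M") for bed, _ in self.intervals],
            "rise_time": [rise.strftime("%H:%M") for _, rise in self.intervals],
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tz=None) -> "SleepDiary":
        entries = []
        for row in df.itertuples():
            date = pd.Timestamp(row.date, tz=tz)
            bed = date + pd.Timedelta(minutes=parse_clock(row.bed_time))
            rise = date + pd.Timedelta(minutes=parse_clock(row.rise_time))
            if rise <= bed:  # rise time on the following civil day
                rise += pd.Timedelta(days=1)
            entries.append((bed, rise))
        return cls(entries)


def in_bed_mask(series: BandPowerSeries, diary: SleepDiary) -> pd.Series:
    """Nullable-boolean mask: True in bed, False out of bed, NA undefined.

    A sample is undefined when no diary interval covers its civil day (the
    day of the sample or, for post-midnight samples, the preceding day whose
    interval might still be running).
    """
    ts = series.timestamps
    mask = pd.Series(pd.NA, index=ts, dtype="boolean")
    if len(series) == 0:
        return mask
    in_bed = np.zeros(len(ts), dtype=bool)
    day_of = ts.normalize()
    covered_days = []
    for bed, rise in diary.intervals:
        if bed.tzinfo is None and ts.tz is not None:
            bed = bed.tz_localize(ts.tz)
            rise = rise.tz_localize(ts.tz)
        in_bed |= np.asarray((ts >= bed) & (ts < rise))
        # the entry defines the mask for every civil day it touches
        covered_days += [bed.normalize(), rise.normalize()]
    covered = np.asarray(day_of.isin(covered_days))
    mask[covered] = in_bed[covered]
    return mask


@dataclass
class AlignedTraces:
    """Per-day value traces on a common lag grid around a daily event."""

    lags_min: np.ndarray
    traces: np.ndarray            # (n_days, n_lags), NaN = missing
    day_labels: pd.DatetimeIndex
    mean_trace: np.ndarray = field(init=False)

    def __post_init__(self):
        with np.errstate(invalid="ignore"):
            self.mean_trace = np.nanmean(self.traces, axis=0)

    def to_frame(self) -> pd.DataFrame:
        n_days, n_lags = self.traces.shape
        return pd.DataFrame({
            "date": np.repeat([d.date() for d in self.day_labels], n_lags),
            "lag_minutes": np.tile(self.lags_min, n_days),
            "value": self.traces.ravel(),
        })


def _event_timestamp(day: pd.Timestamp, event_times, tz) -> pd.Timestamp | None:
    """Resolve the event instant for a civil day from flexible input."""
    if isinstance(event_times, (str, int, float)):
        return day + pd.Timedelta(minutes=parse_clock(event_times))
    if isinstance(event_times, dict):
        key = day.date()
        if key in event_times:
            return day + pd.Timedelta(minutes=parse_clock(event_times[key]))
        return None
    # otherwise an iterable of timestamps
    for t in event_times:
        t = pd.Timestamp(t)
        if t.tzinfo is None and tz is not None:
            t = t.tz_localize(tz)
        if t.normalize() == day:
            return t
    return None


def align_to_daily_event(series: BandPowerSeries, event_times,
                         lag_window_min: float = 360.0) -> AlignedTraces:
    """Re-index each day's samples by lag to that day's event.

    ``event_times`` may be a single clock time (applied every day), a dict
    mapping dates to clock times, or an iterable of timestamps.  The lag
    grid spans ±``lag_window_min`` at the series' sample interval; each
    day's samples are snapped to the nearest lag slot (within half an
    interval).  Negative lags precede the event.
    """
    if len(series) == 0:
        raise AnalysisError("cannot align an empty series")
    interval = series.sample_interval.total_seconds() / 60.0
    lags = np.arange(-lag_window_min, lag_window_min + interval / 2, interval)
    codes, days = series.day_codes()
    days = pd.DatetimeIndex(days)
    traces, used_days = [], []
    minutes_since_epoch = series.timestamps.asi8 / (60 * 1e9)
    for d_idx, day in enumerate(days):
        event = _event_timestamp(day, event_times, series.tz)
        if event is None:
            continue
        if event.tzinfo is None and series.tz is not None:
            event = event.tz_localize(series.tz)
        lag = minutes_since_epoch - event.value / (60 * 1e9)
        slot = np.round((lag - lags[0]) / interval).astype(int)
        near = np.abs(lag - (lags[0] + slot * interval)) <= interval / 2 + 1e-9
        ok = near & (slot >= 0) & (slot < lags.size)
        if not ok.any():
            continue
        sums = np.bincount(slot[ok], weights=series.values[ok],
                           minlength=lags.size)
        hits = np.bincount(slot[ok], minlength=lags.size)
        with np.errstate(invalid="ignore"):
            row = np.where(hits > 0, sums / np.maximum(hits, 1), np.nan)
        traces.append(row)
        used_days.append(day)
    if not traces:
        raise AnalysisError("no alignment events inside the series span")
    return AlignedTraces(lags, np.vstack(traces), pd.DatetimeIndex(used_days))


def sleep_wake_contrast(series: BandPowerSeries, diary: SleepDiary,
                        ) -> tuple[float, float, float]:
    """Mean power in bed, out of bed, and their ratio (in/out).

    Samples on days not covered by the diary are excluded.
    """
    mask = in_bed_mask(series, diary)
    defined = mask.notna().to_numpy()
    if not defined.any():
        raise AnalysisError("diary does not cover any series days")
    in_bed = mask.fillna(False).to_numpy() & defined
    out_bed = (~mask.fillna(True).to_numpy()) & defined
    if not in_bed.any() or not out_bed.any():
        raise AnalysisError("need samples both in and out of bed")
    mean_in = float(series.values[in_bed].mean())
    mean_out = float(series.values[out_bed].mean())
    return mean_in, mean_out, mean_in / mean_out


@dataclass
class DayNightSummary:
    """Distributions of day-time vs night-time band power.

    Includes log10 transforms, quartiles and full range, the percentile of
    an optional in-clinic measurement within the daytime distribution, and
    a 1-vs-2-component Gaussian-mixture BIC check for daytime bimodality
    (clustered movement-artifact contamination produces a second mode).
    """

    day_values: np.ndarray
    night_values: np.ndarray
    day_window: tuple
    night_window: tuple
    in_clinic_value: float | None = None
    in_clinic_percentile: float | None = None
    daytime_bimodal: bool = False
    bic_one: float = float("nan")
    bic_two: float = float("nan")

    @property
    def day_log10(self) -> np.ndarray:
        return np.log10(self.day_values)

    @property
    def night_log10(self) -> np.ndarray:
        return np.log10(self.night_values)

    def percentiles(self) -> pd.DataFrame:
        rows = {}
        for name, vals in (("day", self.day_values),
                           ("night", self.night_values)):
            rows[name] = {
                "p25": np.percentile(vals, 25),
                "p50": np.percentile(vals, 50),
                "p75": np.percentile(vals, 75),
                "min": vals.min(), "max": vals.max(), "n": vals.size,
            }
        return pd.DataFrame(rows).T


def _window_mask(series: BandPowerSeries, window) -> np.ndarray:
    start, end = parse_clock(window[0]), parse_clock(window[1])
    rel = (series.clock_minutes - start) % _MIN_PER_DAY
    return rel < ((end - start) % _MIN_PER_DAY)


def day_night_summary(series: BandPowerSeries,
                      in_clinic_value: float | None = None,
                      day_window=DAY_WINDOW, night_window=NIGHT_WINDOW,
                      random_state: int = 0) -> DayNightSummary:
    """Summarise day-time vs night-time power distributions.

    Values must be positive (device power readouts are); log10 is taken on
    the raw values.  The in-clinic value's percentile is located within the
    daytime distribution.
    """
    day = series.values[_window_mask(series, day_window)]
    night = series.values[_window_mask(series, night_window)]
    if day.size == 0 or night.size == 0:
        raise AnalysisError("no samples in the day or night clock window")
    if day.min() <= 0 or night.min() <= 0:
        raise AnalysisError("day/night summary requires positive power values")
    pct = None
    if in_clinic_value is not None:
        pct = float(sps.percentileofscore(day, in_clinic_value, kind="mean"))
    logday = np.log10(day).reshape(-1, 1)
    g1 = GaussianMixture(1, random_state=random_state).fit(logday)
    g2 = GaussianMixture(2, n_init=5, random_state=random_state).fit(logday)
    bic1, bic2 = float(g1.bic(logday)), float(g2.bic(logday))
    # bimodal = two well-separated components preferred by BIC
    bimodal = False
    if bic2 < bic1:
        mu = np.sort(g2.means_.ravel())
        sd = np.sqrt(g2.covariances_.ravel())
        sep = (mu[1] - mu[0]) / np.sqrt(sd.mean() ** 2)
        bimodal = bool(sep > 2.0 and g2.weights_.min() > 0.05)
    return DayNightSummary(day, night, tuple(day_window), tuple(night_window),
                           in_clinic_value, pct, bimodal, bic1, bic2)
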