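"""Timestamped chronic band-power series.

The central container of the package: one band-power value per ~10-minute
epoch for a single hemisphere and frequency band, as logged by a chronically
sensing DBS device.  Timestamps are timezone-aware instants (devices log UTC;
civil-time analyses convert to the patient's local zone first).
"""

from __future__ import annotations

from dataclasses import dataclass
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["BandSpec", "BandPowerSeries", "parse_clock", "format_clock"]


@dataclass(frozen=True)
class BandSpec:
    """A sensing band: centre frequency, width, and a conventional name."""

    center_hz: float = 25.0
    width_hz: float = 5.0
    name: str = ""

    def __post_init__(self):
        if self.center_hz <= 0 or self.width_hz <= 0:
            raise ValidationError("band centre and width must be positive")
        if not self.name:
            object.__setattr__(self, "name", infer_band_name(self.center_hz))

    @property
    def low_hz(self) -> float:
        return self.center_hz - self.width_hz / 2.0

    @property
    def high_hz(self) -> float:
        return self.center_hz + self.width_hz / 2.0


def infer_band_name(center_hz: float) -> str:
    if 4.0 <= center_hz <= 8.0:
        return "theta"
    if 13.0 <= center_hz <= 35.0:
        return "beta"
    return "band"


def parse_clock(clock) -> float:
    """Parse a clock time ('HH:MM' or 'HH:MM:SS', or minutes) to minutes of day."""
    if isinstance(clock, (int, float, np.integer, np.floating)):
        m = float(clock)
    else:
        parts = str(clock).split(":")
        if not 1 <= len(parts) <= 3:
            raise ValidationError(f"cannot parse clock time {clock!r}")
        try:
            nums = [float(p) for p in parts]
        except ValueError as exc:
            raise ValidationError(f"cannot parse clock time {clock!r}") from exc
        m = nums[0] * 60.0 + (nums[1] if len(nums) > 1 else 0.0) + (
            nums[2] / 60.0 if len(nums) > 2 else 0.0
        )
    if not 0.0 <= m < 24 * 60:
        raise ValidationError(f"clock time {clock!r} outside [00:00, 24:00)")
    return m


def format_clock(minutes: float) -> str:
    minutes = float(minutes) % (24 * 60)
    h, m = divmod(int(round(minutes)), 60)
    return f"{h % 24:02d}:{m:02d}"


class BandPowerSeries:
    """One hemisphere/band chronic band-power stream.

    Parameters
    ----------
    timestamps : pandas.DatetimeIndex
        Strictly increasing, timezone-aware instants (naive input is taken
        as UTC, matching device exports).
    values : array-like of float
        Band power per epoch.  Raw device readouts are in µVp and
        nonnegative; derived series (z-scores, residuals) may be negative.
    subject_id, hemisphere, band
        Metadata carried through every transformation.
    sample_interval : pandas.Timedelta
        Nominal epoch length (default 10 min).
    """

    __slots__ = ("timestamps", "values", "subject_id", "hemisphere", "band",
                 "sample_interval")

    def __init__(self, timestamps, values, *, subject_id: str = "sim",
                 hemisphere: str = "left", band: BandSpec | None = None,
                 sample_interval=pd.Timedelta(minutes=10)):
        idx = pd.DatetimeIndex(timestamps)
        if idx.tz is None:
            idx = idx.tz_localize("UTC")
        vals = np.asarray(values, dtype=float)
        if len(idx) != len(vals):
            raise ValidationError(
                f"{len(idx)} timestamps but {len(vals)} values")
        if len(idx) > 1 and not idx.is_monotonic_increasing:
            raise ValidationError("timestamps must be increasing")
        if len(idx) > 1 and idx.has_duplicates:
            raise ValidationError("timestamps must be strictly increasing")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValidationError("values must be finite")
        if hemisphere not in ("left", "right"):
            raise ValidationError(f"hemisphere must be left/right, got {hemisphere!r}")
        self.timestamps = idx
        self.values = vals
        self.subject_id = str(subject_id)
        self.hemisphere = hemisphere
        self.band = band if band is not None else BandSpec()
        self.sample_interval = pd.Timedelta(sample_interval)

    # ------------------------------------------------------------------ basics
    def __len__(self) -> int:
        return len(self.values)

    def __repr__(self) -> str:
        span = ""
        if len(self):
            span = f", {self.timestamps[0]} .. {self.timestamps[-1]}"
        return (f"<BandPowerSeries {self.subject_id}/{self.hemisphere}/"
                f"{self.band.name}: n={len(self)}{span}>")

    def with_values(self, values) -> "BandPowerSeries":
        """Copy of this series with ``values`` replaced (metadata kept)."""
        return BandPowerSeries(self.timestamps, values,
                               subject_id=self.subject_id,
                               hemisphere=self.hemisphere, band=self.band,
                               sample_interval=self.sample_interval)

    def require_nonnegative(self) -> "BandPowerSeries":
        if self.values.size and self.values.min() < 0:
            i = int(np.argmin(self.values))
            raise ValidationError(
                f"negative power {self.values[i]} at record {i} "
                f"({self.timestamps[i]})")
        return self

    # --------------------------------------------------------------- civil time
    @property
    def tz(self):
        return self.timestamps.tz

    def tz_convert(self, tz_name: str) -> "BandPowerSeries":
        """Relabel instants in an IANA zone (the instants are unchanged)."""
        try:
            zone = ZoneInfo(str(tz_name))
        except Exception as exc:  # zoneinfo raises several types
            raise ValidationError(f"unknown timezone {tz_name!r}") from exc
        return BandPowerSeries(self.timestamps.tz_convert(zone), self.values,
                               subject_id=self.subject_id,
                               hemisphere=self.hemisphere, band=self.band,
                               sample_interval=self.sample_interval)

    @property
    def clock_minutes(self) -> np.ndarray:
        """Civil clock time of each sample, in minutes of the local day."""
        idx = self.timestamps
        return (idx.hour.to_numpy() * 60.0 + idx.minute.to_numpy()
                + idx.second.to_numpy() / 60.0)

    @property
    def local_dates(self) -> np.ndarray:
        """Civil date label of each sample (local midnight-to-midnight days)."""
        return self.timestamps.normalize().to_numpy()

    def day_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer code per sample identifying its civil day, plus the days."""
        codes, uniques = pd.factorize(self.timestamps.normalize())
        return codes, uniques

    # ------------------------------------------------------------------ export
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timestamp": self.timestamps,
            "value": self.values,
        })

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.timestamps, name=self.band.name)
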