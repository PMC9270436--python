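"""Preprocessing of chronic band-power streams.

Chronic sensing streams contain sporadic extreme values (movement/device
transients) and slow multi-day drift.  The standard pipeline is:

1. **Iterative outlier interpolation** — any sample whose z-score exceeds 6
   (two-sided by default) is replaced by linear interpolation between its
   nearest non-outlier neighbours; the z-scores are recomputed and the rule
   re-applied until no sample exceeds the threshold.
2. **z-scoring** for cross-patient display.
3. **Daily detrending** — each local civil day's samples are divided by that
   day's median (or mean), so every day has central value 1 and slow drift
   cannot masquerade as diurnal structure.

All steps preserve length and timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, ValidationError
from .series import BandPowerSeries

__all__ = ["PreprocessReport", "remove_outliers", "zscore", "detrend_daily"]


@dataclass
class PreprocessReport:
    """Bookkeeping for outlier interpolation."""

    n_outliers_replaced: int = 0
    n_iterations: int = 0
    replaced_indices: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.n_outliers_replaced != len(self.replaced_indices):
            raise ValidationError("outlier count does not match index list")


def _interpolate_flagged(values: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    """Replace flagged samples by linear interpolation between the nearest
    unflagged neighbours (index-based); endpoints take the nearest valid value."""
    out = values.copy()
    idx = np.arange(len(values))
    good = ~flagged
    # np.interp extrapolates flat beyond the first/last good sample, which is
    # exactly the documented endpoint rule.
    out[flagged] = np.interp(idx[flagged], idx[good], values[good])
    return out


def remove_outliers(series: BandPowerSeries, z_threshold: float = 6.0,
                    two_sided: bool = True, max_iter: int = 100,
                    ) -> tuple[BandPowerSeries, PreprocessReport]:
    """Iteratively replace outlying samples by neighbour interpolation.

    A sample is an outlier when its z-score — computed from the current
    series' mean and sample standard deviation (ddof=1) — exceeds
    ``z_threshold`` (``|z|`` if ``two_sided``, else ``z`` alone).  Outliers
    are replaced by linear interpolation between their nearest non-outlier
    neighbours and the rule is re-applied until none remain.

    Returns the cleaned series and a :class:`PreprocessReport`.  A series of
    zero variance is returned unchanged.
    """
    if len(series) < 3:
        raise AnalysisError("outlier removal needs at least 3 samples")
    values = series.values.copy()
    replaced: set[int] = set()
    n_iter = 0
    for _ in range(max_iter):
        sd = values.std(ddof=1)
        if sd == 0:
            break
        z = (values - values.mean()) / sd
        flagged = (np.abs(z) > z_threshold) if two_sided else (z > z_threshold)
        if not flagged.any():
            break
        if flagged.all():
            raise AnalysisError("every sample flagged as outlier; "
                                "z threshold too low for this series")
        values = _interpolate_flagged(values, flagged)
        replaced.update(np.flatnonzero(flagged).tolist())
        n_iter += 1
    report = PreprocessReport(len(replaced), n_iter, sorted(replaced))
    return series.with_values(values), report


def zscore(series: BandPowerSeries) -> BandPowerSeries:
    """Standardise to mean 0, SD 1 (sample SD, ddof=1)."""
    sd = series.values.std(ddof=1)
    if not sd > 0:
        raise AnalysisError("cannot z-score a zero-variance series")
    return series.with_values((series.values - series.values.mean()) / sd)


def detrend_daily(series: BandPowerSeries, statistic: str = "median",
                  ) -> BandPowerSeries:
    """Divide each local civil day's values by that day's central statistic.

    With ``statistic='median'`` (default) every day of the result has median
    exactly 1; the ``'mean'`` variant normalises each day to mean 1 instead.
    Days run midnight-to-midnight in the series' attached timezone.
    """
    if statistic not in ("median", "mean"):
        raise ValidationError(f"statistic must be median or mean, got {statistic!r}")
    if len(series) == 0:
        return series.with_values(series.values)
    codes, days = series.day_codes()
    values = series.values
    grouped = pd.Series(values).groupby(codes)
    stat = (grouped.median() if statistic == "median" else grouped.mean())
    stat_arr = stat.to_numpy()
    bad = ~(stat_arr > 0)
    if bad.any():
        day = pd.Timestamp(days[np.flatnonzero(bad)[0]]).date()
        raise AnalysisError(f"daily {statistic} is not positive on {day}; "
                            "cannot detrend")
    return series.with_values(values / stat_arr[codes])
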