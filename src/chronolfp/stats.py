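"""Small-sample statistics for paired band-power summaries.

Pearson correlation between concurrently sensed (detrended) bands, an exact
two-sided Wilcoxon signed-rank test, and the paired t-test.  Sample sizes
here are tiny (a handful of hemispheres), so the signed-rank null is
evaluated exactly: all 2^n equally likely sign assignments of the ranks are
enumerated (via the standard convolution over rank sums, which counts the
same 2^n patterns without materialising them) rather than by normal
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import AnalysisError, ValidationError
from .series import BandPowerSeries

__all__ = ["PairedSample", "TestResult", "pearson_detrended",
           "wilcoxon_exact", "signed_rank_sf", "paired_t"]


@dataclass
class PairedSample:
    """Paired measurements (e.g. full-24h vs windowed variance explained)."""

    a: np.ndarray
    b: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValidationError("paired samples must be equal-length 1-D")
        if self.a.size < 2:
            raise ValidationError("need at least 2 pairs")

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


@dataclass
class TestResult:
    """Outcome of a two-sided location test."""

    statistic: float
    p_two_sided: float
    method: str
    df: int | None = None
    conf_int: tuple | None = None

    def __post_init__(self):
        if not 0 < self.p_two_sided <= 1:
            raise ValidationError("p-value must be in (0, 1]")


def pearson_detrended(series_a: BandPowerSeries, series_b: BandPowerSeries,
                      ) -> tuple[float, float]:
    """Pearson r (and p) between two detrended series, inner-joined on
    timestamps."""
    common = series_a.timestamps.intersection(series_b.timestamps)
    if len(common) < 3:
        raise AnalysisError("need >= 3 common timestamps for correlation")
    a = series_a.to_pandas().loc[common].to_numpy()
    b = series_b.to_pandas().loc[common].to_numpy()
    if np.var(a) == 0 or np.var(b) == 0:
        raise AnalysisError("zero variance in a joined series")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)


def _rank_sum_counts(scaled_ranks: np.ndarray) -> np.ndarray:
    """Counts of positive-rank-sum values over all 2^n sign assignments.

    ``scaled_ranks`` are integers (mid-ranks doubled when ties are present);
    entry k of the result counts the assignments whose positive-rank sum
    equals k.  Computed by convolving (1 + x^r) over the ranks — the
    generating function of the full enumeration.
    """
    total = int(scaled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts = counts + shifted
    return counts


def signed_rank_sf(w: float, ranks: np.ndarray) -> tuple[float, float]:
    """Exact P(W >= w) and P(W <= w) for the positive-rank-sum statistic."""
    ranks = np.asarray(ranks, dtype=float)
    scale = 2 if np.any(ranks % 1 != 0) else 1
    scaled = np.round(ranks * scale).astype(int)
    counts = _rank_sum_counts(scaled)
    n_patterns = counts.sum()
    ws = int(round(w * scale))
    upper = counts[ws:].sum() / n_patterns
    lower = counts[:ws + 1].sum() / n_patterns
    return float(upper), float(lower)


def wilcoxon_exact(sample: PairedSample | None = None, *,
                   w: float | None = None, n: int | None = None,
                   ) -> TestResult:
    """Exact two-sided Wilcoxon signed-rank test.

    Accepts either a :class:`PairedSample` (zero differences dropped,
    mid-ranks for ties) or a precomputed statistic via ``w=..., n=...``
    (ranks 1..n assumed untied).  W is the sum of positive ranks; the
    two-sided p doubles the smaller exact tail, capped at 1.

    Exact enumeration is practical for n <= 25 (the implementation caps
    there; beyond that a normal approximation would be the standard tool).
    """
    if sample is not None:
        d = sample.differences
        d = d[d != 0]
        if d.size == 0:
            raise AnalysisError("all differences are zero")
        ranks = sps.rankdata(np.abs(d))
        w_stat = float(ranks[d > 0].sum())
    else:
        if w is None or n is None:
            raise ValidationError("provide a PairedSample or both w and n")
        if n < 1:
            raise ValidationError("n must be >= 1")
        ranks = np.arange(1, n + 1, dtype=float)
        w_stat = float(w)
    if ranks.size > 25:
        raise AnalysisError("exact enumeration supported for n <= 25")
    upper, lower = signed_rank_sf(w_stat, ranks)
    p = min(1.0, 2.0 * min(upper, lower))
    return TestResult(w_stat, p, "wilcoxon-signed-rank-exact")


def paired_t(sample: PairedSample) -> TestResult:
    """Two-sided paired t-test with a 95% CI for the mean difference."""
    d = sample.differences
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        raise AnalysisError("zero-variance differences; t undefined")
    se = sd / np.sqrt(n)
    t = float(d.mean() / se)
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    half = float(sps.t.ppf(0.975, df) * se)
    return TestResult(t, p, "paired-t", df=df,
                      conf_int=(float(d.mean() - half), float(d.mean() + half)))
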