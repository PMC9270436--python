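# Methods

This note documents the models and procedures implemented in `chronolfp`,
the choices made where several reasonable options existed, and what the
synthetic-data tests do and do not establish about real recordings.

## The data model

A chronic band-power stream is a sequence of nonnegative µVp values, one per
nominal 10-minute epoch, with timezone-aware timestamps. Devices log UTC;
all civil-time operations (daily detrending, clock binning, day/night
windows) are defined on the clock labels after conversion to the patient's
IANA zone, so a daylight-saving transition day simply contains 23 or 25
hours of samples and is binned by its local labels. Gaps are preserved, not
imputed, except where the periodogram explicitly resamples (below).

## Preprocessing

**Outlier interpolation.** A sample is an outlier when its z-score exceeds 6.
z-scores use the full-series mean and *sample* SD (ddof = 1), recomputed on
every iteration; flagged samples are replaced by linear interpolation
(index-based) between the nearest non-outlier neighbours, and the rule is
re-applied until no sample exceeds the threshold. Choices the procedure
itself does not pin down: the rule is two-sided (|z| > 6) by default because
post-normalisation deflections can point either way, with a `two_sided=False`
flag for the one-sided reading; endpoint outliers take the nearest valid
value; a zero-variance series is returned unchanged. The iteration is
idempotent — a cleaned series passes through unchanged — and never alters
length or timestamps.

**Daily detrending.** Each local civil day's values are divided by that
day's median (so the day's median becomes exactly 1); a mean-normalising
variant is provided for cross-band correlation work. Detrending removes
multi-day drift so that within-day structure and cross-band correlation are
not dominated by slow trends.

## The time-of-day model and variance explained

The 24-h clock is divided into 30-minute bins; the fit value in each bin is
the mean of all samples (across days) falling in it, and the fit at an
arbitrary clock time is the linear interpolation between the two adjacent
bin centres. Interpolation wraps across midnight by default — clock time is
circular — with a non-wrapping mode for comparison. Empty bins are bridged
by interpolating between their nearest non-empty neighbours; at least two
non-empty bins are required.

Removing the influence of time of day means subtracting the fit value at
each sample's clock time; the variance explained is

    VE = (var_total − var_residual) / var_total

with population variances throughout. VE can in principle be slightly
negative (a fit transferred from unrelated data, or pathological binning);
it is reported as-is, never clamped. Windowed VE (day-only or night-only)
restricts both the samples and the bins to the clock window and uses a
non-circular fit over the window; the degenerate full-day window reduces
exactly to the unwindowed quantity.

## The temporal shuffling test

Each surrogate applies to every civil day an independent circular shift of
its samples' clock times by a uniform whole number of sample intervals
(0–24 h; 144 offsets at 10-min sampling — the granularity is a choice, the
procedure is defined only up to "a random shift"). Shifting clock labels
rather than values handles missing samples naturally and preserves each
day's internal structure while destroying cross-day clock alignment. VE is
recomputed for every surrogate by the same fit procedure, and

    p = (1 + #{VE_null ≥ VE_obs}) / (1 + n_shuffles)

(the add-one rule), so 1000 surrogates give an attainable floor of 1/1001 ≈
0.001. The implementation is vectorised across surrogates (scatter-added
bin means on a surrogates × samples matrix, chunked to bound memory), which
keeps a 200-run type-I calibration suite to a couple of minutes on one CPU.

## Periodicity

The series is placed on its regular nominal grid; gaps up to 2 h (default)
are linearly interpolated, longer gaps split the record into chunks whose
Welch estimates are averaged with length weights. Welch uses Hann windows
of 4 days with 50% overlap and per-segment constant detrending; 4-day
windows place a 24-h period exactly on a frequency bin. Power is normalised
to unit total and reported over periods in hours; the dominant period is
the power maximum over [2 h, half the record length].

## Sleep/wake epochs

Diary entries are (bed, rise) instants; intervals may cross midnight. The
in-bed mask is a nullable boolean: days no diary entry touches are
*undefined* and excluded from masked statistics rather than imputed.
Alignment to a daily event re-indexes each day's samples by lag to that
day's event on a ±6 h (default) grid at the sample interval, averaging
samples that snap to the same lag slot; the mean trace ignores missing
cells. Day (08:00–20:00) and night (00:00–06:00) windows are the
conventional defaults and overridable. The day/night summary reports
quartiles, ranges, log10 transforms, and the percentile of an optional
in-clinic measurement within the daytime distribution. "Strong daytime
bimodality" — the signature of clustered movement/dyskinesia artifacts —
is operationalised as a 1-vs-2-component Gaussian mixture on log10 daytime
values compared by BIC, accepted only when the two components are well
separated (mean separation > 2 pooled SDs, minor weight > 5%); this is a
simple, testable stand-in for a qualitative visual judgement.

## Raw LFP band power

Filtering is a 4th-order Butterworth band-pass (4–98 Hz corners) applied
forward–backward for zero phase. Band power of a segment is 2√2 × RMS of
the band-filtered segment — a peak-to-peak-equivalent convention under
which a pure in-band sinusoid of amplitude A reads 2A. The on-device µVp
measure is proprietary, so absolute values here are internally consistent
but not device-comparable; percentages of resting power are the supported
quantity. The movement table averages epochs of one label with equal weight
per epoch (not per sample — another undocumented degree of freedom, fixed
and stated). The global wavelet spectrum uses a complex Morlet mother
wavelet over 64 log-spaced frequencies 4–98 Hz, time-averaged power.

## Small-sample tests

The exact Wilcoxon signed-rank test drops zero differences, mid-ranks ties,
and evaluates the null by the generating-function convolution over rank
sums — an exact count of all 2^n sign assignments, feasible to n = 25
(mid-ranks are doubled to integers first). The two-sided p doubles the
smaller tail, capped at 1. The paired t-test reports t on n−1 df with a
95% CI for the mean difference. Pearson correlation between concurrent
bands inner-joins on timestamps and expects both series detrended.

## The synthetic generator

One stream is x(t) = p(t) · exp(σ ε(t) − σ²/2) with ε i.i.d. standard
normal: multiplicative, mean-one lognormal noise (band power is nonnegative
and right-skewed; log-scale histograms of real daytime values look roughly
Gaussian) of coefficient of variation `noise_cv`. The clock profile p joins
a day level and a night level with logistic ramps at the sleep-window edges
(`transition_min` ≈ the 10–90% rise distance, default 30 min), optionally
modulated by a smooth 24-h sinusoid and a slow linear drift. Defaults — 30
days, day 4 µVp vs night 2 µVp, sleep 23:00–07:00, CV 0.3, spike
probability 10⁻³ at 5× the day level — represent a realistic month of
subthalamic sensing with a 2:1 wake/sleep contrast; spikes are drawn large
enough to trip the |z| > 6 rule when enabled.

Because p is deterministic, the diurnal variance fraction has the closed
form f = Var(p) / (Var(p) + σ_cv² E[p²]) (drift excluded), inverted by
`noise_cv_for_fraction` to build streams whose true fraction is known —
this is how parameter-recovery and shuffle-floor tests fix ground truth at,
e.g., 0.40.

Dual-band streams share one timestamp grid; their log-noises mix a common
standard-normal driver with band-specific ones in proportion √w : √(1−w),
so `artifact_weight` w = 0 gives independent noise and w = 1 a fully shared
broadband driver. Daytime-only artifact bursts (Poisson starts, exponential
durations, a common multiplier on both bands) emulate clustered
movement/dyskinesia contamination and produce the bimodal daytime
distribution. Each stochastic component uses its own child generator, so
enabling bursts does not perturb the noise realisation. Raw LFP streams sum
a sinusoid at the beta peak, 1/f^exponent background noise, and tapered
broadband transients during labelled epochs whose spectra are tilted to low
frequencies (power ~ 1/f^1.5), reproducing the empirical pattern that
movement artifacts inflate theta estimates at least as much as beta.

**What the generator does not emulate:** the device's proprietary on-chip
averaging, stimulation and ECG artifact spectra, medication-cycle
structure, and any amplitude distribution fitted to real patients. Passing
tests therefore demonstrate correctness of the *procedures* under a
controlled model, not clinical properties of any patient population;
patient-level summaries (mean VE across hemispheres, cross-band r ranges,
absolute movement-table values) depend on private clinical data and are
deliberately not targets.

## Problem sizes and numerics

Simulation-based tests use 30-day streams at 10-min sampling (4320
samples), 20 seeds for means, 200 runs for the type-I calibration of the
shuffle test, and 1000 surrogates per test — sizes at which Monte-Carlo
error is well below the tolerances asserted. Degenerate inputs (zero
variance, empty windows, <2 days, all-flagged outliers) raise typed errors
rather than returning NaN. Tolerances in tests are derived from the
construction (machine precision for algebraic identities, 3 Monte-Carlo
standard errors for sampling checks, ±0.05 for 20-seed means of VE).

## Known limitations

- The fit treats empty clock bins by interpolation; long systematic gaps
  (e.g. a charger-off window every night) bias the profile there.
- VE uses the in-sample fit, so it is mildly optimistic for short records
  (the shuffle test accounts for this by applying the same procedure to
  surrogates).
- The periodogram's gap handling assumes missingness is unrelated to the
  signal.
- The exact signed-rank test is limited to n ≤ 25; larger samples should
  use a normal approximation, which this package deliberately omits.
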