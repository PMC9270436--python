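"""Raw LFP stream processing: filtering, spectra, band power, movement table.

Implements the in-clinic analysis chain for raw 250 Hz LFP recordings made
while the patient performs scripted movements: a 4–98 Hz zero-phase
band-pass, Welch and global Morlet-wavelet spectra, band power in the
chronic-sensing bands (a 5 Hz window around the beta peak; 4–8 Hz theta),
and a per-movement power table expressed as a percentage of resting power.

Band power uses a peak-to-peak-equivalent convention: ``2·√2 × RMS`` of the
band-filtered segment, so a pure in-band sinusoid of amplitude A reads as
2A.  The device's proprietary µVp readout is not public; absolute values
are therefore internally consistent but not device-comparable, and the
percentage-of-rest quantities are the supported comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal

from .exceptions import AnalysisError, ValidationError

__all__ = ["LfpStream", "MovementAnnotation", "BandDefinition",
           "filter_lfp", "welch_spectrum", "global_wavelet_spectrum",
           "band_power", "movement_power_table", "MOVEMENT_LABELS"]

MOVEMENT_LABELS = (
    "rest", "walk", "turn", "stand", "sit", "stand up", "sit down",
    "arm swing", "arm lift", "arms to chest", "trunk bend", "trunk rotate",
    "head nod", "head shake", "head tilt",
)


@dataclass
class LfpStream:
    """A single-channel raw LFP recording (µV)."""

    sample_rate: float
    samples: np.ndarray
    start_time: pd.Timestamp | None = None
    channel: str = ""

    def __post_init__(self):
        if not self.sample_rate > 0:
            raise ValidationError("sample_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValidationError("LFP samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def segment(self, start_s: float, end_s: float) -> np.ndarray:
        if start_s < 0 or end_s > self.duration_s + 1e-9:
            raise AnalysisError(
                f"epoch [{start_s}, {end_s}] s outside stream span "
                f"[0, {self.duration_s:.2f}] s")
        i0 = int(round(start_s * self.sample_rate))
        i1 = int(round(end_s * self.sample_rate))
        return self.samples[i0:i1]


@dataclass(frozen=True)
class MovementAnnotation:
    """One labelled movement epoch, in seconds from stream start."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"epoch {self.label!r} must have end > start")


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band for power estimation."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz <= 98.0:
            raise ValidationError(
                f"band {self.name!r} must satisfy 0 < low < high <= 98 Hz")

    @classmethod
    def around_peak(cls, peak_hz: float, width_hz: float = 5.0,
                    name: str = "beta") -> "BandDefinition":
        return cls(name, peak_hz - width_hz / 2, peak_hz + width_hz / 2)


THETA = BandDefinition("theta", 4.0, 8.0)


def _bandpass_sos(low: float, high: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if high >= nyq:
        raise AnalysisError(
            f"low-pass corner {high} Hz must lie below Nyquist ({nyq} Hz)")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs,
                         output="sos")


def filter_lfp(stream: LfpStream, hp: float = 4.0, lp: float = 98.0,
               order: int = 4) -> LfpStream:
    """Zero-phase Butterworth band-pass (default 4–98 Hz); removes DC."""
    sos = _bandpass_sos(hp, lp, stream.sample_rate, order)
    filtered = signal.sosfiltfilt(sos, stream.samples)
    return LfpStream(stream.sample_rate, filtered, stream.start_time,
                     stream.channel)


def welch_spectrum(stream: LfpStream, segment_s: float = 1.0,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density (Hann windows, 50% overlap)."""
    nperseg = int(round(segment_s * stream.sample_rate))
    if stream.samples.size < 2 * nperseg:
        raise AnalysisError("stream too short for Welch estimate "
                            f"(need >= {2 * nperseg} samples)")
    freqs, psd = signal.welch(stream.samples, fs=stream.sample_rate,
                              window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2, detrend="constant")
    return freqs, psd


def global_wavelet_spectrum(segment: np.ndarray, sample_rate: float,
                            f_min: float = 4.0, f_max: float = 98.0,
                            n_freqs: int = 64,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged Morlet wavelet power over log-spaced frequencies.

    Uses a complex Morlet mother wavelet; power is the squared magnitude of
    the continuous transform averaged across the segment (arbitrary units).
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < sample_rate:
        raise AnalysisError("wavelet spectrum needs a segment of >= 1 s")
    freqs = np.geomspace(f_min, f_max, n_freqs)
    wavelet = "cmor1.5-1.0"
    fc = pywt.central_frequency(wavelet)
    scales = fc * sample_rate / freqs
    coefs, _ = pywt.cwt(segment, scales, wavelet,
                        sampling_period=1.0 / sample_rate)
    power = np.mean(np.abs(coefs) ** 2, axis=1)
    return freqs, power


def band_power(segment: np.ndarray, band: BandDefinition,
               sample_rate: float) -> float:
    """Peak-to-peak-equivalent band power: 2√2 × RMS of the band-filtered
    segment (µVp-equivalent; a sinusoid of amplitude A in-band reads 2A)."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise AnalysisError("cannot estimate band power of an empty segment")
    sos = _bandpass_sos(band.low_hz, band.high_hz, sample_rate)
    filtered = signal.sosfiltfilt(sos, segment)
    rms = float(np.sqrt(np.mean(filtered ** 2)))
    return 2.0 * np.sqrt(2.0) * rms


def movement_power_table(stream: LfpStream,
                         annotations: list[MovementAnnotation],
                         beta_band: BandDefinition,
                         theta_band: BandDefinition = THETA,
                         rest_label: str = "rest") -> pd.DataFrame:
    """Per-movement band power, absolute and as a percentage of rest.

    Epochs sharing a label are averaged with equal weight per epoch.  The
    rest row anchors the relative columns at exactly 100%.

    Returns a DataFrame indexed by movement label with columns
    ``beta_uvp, beta_pct_rest, theta_uvp, theta_pct_rest, n_epochs``.
    """
    if not annotations:
        raise AnalysisError("no movement annotations supplied")
    by_label: dict[str, list[MovementAnnotation]] = {}
    for ann in annotations:
        by_label.setdefault(ann.label, []).append(ann)
    if rest_label not in by_label:
        raise AnalysisError(f"no {rest_label!r} epoch: relative power "
                            "needs a resting baseline")
    rows = {}
    for label, epochs in by_label.items():
        beta_vals, theta_vals = [], []
        for ep in epochs:
            seg = stream.segment(ep.start_s, ep.end_s)
            beta_vals.append(band_power(seg, beta_band, stream.sample_rate))
            theta_vals.append(band_power(seg, theta_band, stream.sample_rate))
        rows[label] = (float(np.mean(beta_vals)), float(np.mean(theta_vals)),
                       len(epochs))
    rest_beta, rest_theta, _ = rows[rest_label]
    if rest_beta == 0 or rest_theta == 0:
        raise AnalysisError("resting band power is zero; cannot normalise")
    order = [rest_label] + [l for l in rows if l != rest_label]
    table = pd.DataFrame(
        {
            "beta_uvp": [rows[l][0] for l in order],
            "beta_pct_rest": [100.0 * rows[l][0] / rest_beta for l in order],
            "theta_uvp": [rows[l][1] for l in order],
            "theta_pct_rest": [100.0 * rows[l][1] / rest_theta for l in order],
            "n_epochs": [rows[l][2] for l in order],
        },
        index=pd.Index(order, name="activity"))
    return table


# ------------------------------------------------------------------- raw I/O

def read_lfp_csv(path) -> LfpStream:
    """Read a single-channel LFP CSV with header ``time_s,uv``."""
    df = pd.read_csv(path)
    for col in ("time_s", "uv"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing LFP column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValidationError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValidationError(f"{path}: sampling is not uniform")
    return LfpStream(1.0 / dt[0], df["uv"].to_numpy(dtype=float))


def write_lfp_csv(stream: LfpStream, path) -> None:
    t = np.arange(stream.samples.size) / stream.sample_rate
    pd.DataFrame({"time_s": t, "uv": stream.samples}).to_csv(
        path, index=False, float_format="%.17g")


def read_annotations_csv(path) -> list[MovementAnnotation]:
    """Read movement annotations with header ``label,start_s,end_s``."""
    df = pd.read_csv(path)
    for col in ("label", "start_s", "end_s"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing annotation column {col!r}")
    return [MovementAnnotation(str(r.label), float(r.start_s), float(r.end_s))
            for r in df.itertuples()]
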