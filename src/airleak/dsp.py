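"""Frequency weighting, loudness, spectral analysis and filtering.

Levels are expressed in dB relative to digital full scale (a full-scale square
wave has RMS 1.0 -> 0 dB) plus a configurable ``calibration_offset`` that maps
full scale onto an absolute A-weighted sound pressure level when a calibrator
is available. The default offset of 94 dB corresponds to the common 1 kHz /
94 dB SPL (1 Pa) acoustic calibrator convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .audio_io import AudioSegment

__all__ = [
    "SPLSeries",
    "Spectrogram",
    "PowerSpectrum",
    "a_weighting_gain",
    "apply_a_weighting",
    "spl_series",
    "spectrogram",
    "power_spectrum",
    "highpass",
    "mix_signals",
    "power_density_histogram",
    "DEFAULT_CALIBRATION_OFFSET_DB",
    "SPL_FLOOR_DB",
]

DEFAULT_CALIBRATION_OFFSET_DB = 94.0
#: level assigned to windows with zero signal (dB re full scale, pre-offset)
SPL_FLOOR_DB = -120.0

# IEC 61672 A-weighting pole frequencies (Hz)
_F1, _F2, _F3, _F4 = 20.598997, 107.65265, 737.86223, 12194.217


@dataclass
class SPLSeries:
    """A-weighted sound pressure level (dBA) versus time."""

    times: np.ndarray
    level: np.ndarray
    window_s: float
    hop_s: float
    calibration_offset: float = DEFAULT_CALIBRATION_OFFSET_DB

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.level = np.asarray(self.level, dtype=np.float64)
        if self.times.shape != self.level.shape:
            raise ValueError("times and level must have equal length")
        if not np.all(np.isfinite(self.level)):
            raise ValueError("SPL levels must be finite")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("SPL times must be strictly increasing")


@dataclass
class Spectrogram:
    """Short-time power spectrum in dB re full scale (time x frequency)."""

    times: np.ndarray
    frequencies: np.ndarray
    power: np.ndarray
    window_s: float
    overlap_fraction: float

    def __post_init__(self) -> None:
        if self.power.shape != (self.times.size, self.frequencies.size):
            raise ValueError("power matrix dimensions must match time/frequency axes")
        if not np.all(np.diff(self.frequencies) > 0) or self.frequencies[0] < 0:
            raise ValueError("frequencies must be non-negative ascending")


@dataclass
class PowerSpectrum:
    """Averaged power spectrum of a time window, in dB re full scale."""

    frequencies: np.ndarray
    power: np.ndarray
    source_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if not np.all(np.diff(self.frequencies) > 0):
            raise ValueError("frequencies must be strictly ascending")
        if not np.all(np.isfinite(self.power)):
            raise ValueError("power values must be finite")


def a_weighting_gain(frequency) -> np.ndarray | float:
    """Standard A-weighting gain in dB, normalized to 0 dB at 1 kHz.

    Accepts a scalar or array of frequencies in Hz (all > 0).
    """
    f = np.asarray(frequency, dtype=np.float64)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    f2 = f ** 2
    num = (_F4 ** 2) * f2 ** 2
    den = ((f2 + _F1 ** 2)
           * np.sqrt((f2 + _F2 ** 2) * (f2 + _F3 ** 2))
           * (f2 + _F4 ** 2))
    gain = 20.0 * np.log10(num / den)
    # normalization so the curve passes exactly through 0 dB at 1 kHz
    ref = 1000.0 ** 4 * _F4 ** 2 / (
        (1000.0 ** 2 + _F1 ** 2)
        * np.sqrt((1000.0 ** 2 + _F2 ** 2) * (1000.0 ** 2 + _F3 ** 2))
        * (1000.0 ** 2 + _F4 ** 2))
    gain -= 20.0 * np.log10(ref)
    return float(gain) if np.isscalar(frequency) else gain


def apply_a_weighting(segment: AudioSegment) -> AudioSegment:
    """Apply the A-weighting curve to a segment (zero-phase, FFT domain).

    Each rFFT bin is scaled by the exact A-curve gain at its frequency, so the
    realized response matches :func:`a_weighting_gain` to machine precision at
    every bin; the DC bin is zeroed.
    """
    n = segment.samples.size
    spectrum = np.fft.rfft(segment.samples)
    freqs = np.fft.rfftfreq(n, d=1.0 / segment.sample_rate)
    gains = np.zeros_like(freqs)
    gains[1:] = 10.0 ** (a_weighting_gain(freqs[1:]) / 20.0)
    weighted = np.fft.irfft(spectrum * gains, n=n)
    return AudioSegment(weighted, segment.sample_rate, segment.start_time)


def spl_series(segment: AudioSegment, window_s: float = 0.125,
               hop_s: float = 0.03125,
               calibration_offset: float = DEFAULT_CALIBRATION_OFFSET_DB) -> SPLSeries:
    """A-weighted SPL versus time.

    The segment is A-weighted once, then per-window level is
    ``20*log10(RMS / full scale) + calibration_offset`` over windows of
    ``window_s`` advancing by ``hop_s``. Window times are window centers.
    Defaults follow the sound-level-meter "fast" convention (125 ms window).
    """
    if not (window_s >= hop_s > 0):
        raise ValueError("require window_s >= hop_s > 0")
    nwin = int(round(window_s * segment.sample_rate))
    nhop = int(round(hop_s * segment.sample_rate))
    if nwin < 1 or nhop < 1:
        raise ValueError("window and hop must span at least one sample")
    x = apply_a_weighting(segment).samples
    if x.size < nwin:
        raise ValueError(
            f"segment ({segment.duration:.3f} s) shorter than window ({window_s} s)")
    starts = np.arange(0, x.size - nwin + 1, nhop)
    # vectorized window RMS via cumulative sum of squares
    csum = np.concatenate(([0.0], np.cumsum(x ** 2)))
    mean_sq = (csum[starts + nwin] - csum[starts]) / nwin
    with np.errstate(divide="ignore"):
        level = np.maximum(10.0 * np.log10(mean_sq), SPL_FLOOR_DB) + calibration_offset
    times = segment.start_time + (starts + nwin / 2) / segment.sample_rate
    return SPLSeries(times, level, window_s, hop_s, calibration_offset)


def spectrogram(segment: AudioSegment, window_s: float = 4096 / 44100,
                overlap_fraction: float = 0.5,
                floor_db: float = -100.0) -> Spectrogram:
    """Short-time power spectrogram in dB re full scale, clipped at floor_db.

    Hann window; power scaled so a full-scale on-bin sine reads about -3 dB
    (its mean-square value).
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    nperseg = int(round(window_s * segment.sample_rate))
    if nperseg > segment.samples.size:
        raise ValueError("window longer than signal")
    noverlap = int(nperseg * overlap_fraction)
    freqs, times, sxx = signal.spectrogram(
        segment.samples, fs=segment.sample_rate, window="hann",
        nperseg=nperseg, noverlap=noverlap, scaling="spectrum", mode="psd")
    power_db = np.maximum(10.0 * np.log10(np.maximum(sxx, 1e-30)), floor_db)
    return Spectrogram(times + segment.start_time, freqs, power_db.T,
                       window_s, overlap_fraction)


def power_spectrum(segment: AudioSegment, t0: float | None = None,
                   t1: float | None = None, nperseg: int = 4096,
                   oversample: int = 4) -> PowerSpectrum:
    """Averaged (Welch) power spectrum of the window [t0, t1], dB re full scale.

    ``oversample`` zero-pads each FFT (nfft = oversample * nperseg) to reduce
    scalloping loss on off-bin tones, so tone peak levels are read accurately.
    """
    if t0 is None:
        t0 = segment.start_time
    if t1 is None:
        t1 = segment.start_time + segment.duration
    if not t0 < t1:
        raise ValueError(f"empty analysis window [{t0}, {t1}]")
    window = segment.crop(t0, t1)
    nperseg = min(nperseg, window.samples.size)
    freqs, pxx = signal.welch(
        window.samples, fs=segment.sample_rate, window="hann",
        nperseg=nperseg, noverlap=nperseg // 2,
        nfft=nperseg * oversample, scaling="spectrum")
    power_db = 10.0 * np.log10(np.maximum(pxx, 1e-30))
    return PowerSpectrum(freqs, power_db, (t0, t1))


def highpass(segment: AudioSegment, cutoff_hz: float = 500.0,
             order: int = 4) -> AudioSegment:
    """Zero-phase Butterworth high-pass filter.

    Applied forward-backward (filtfilt), so the -3 dB design point becomes
    -6 dB at the cutoff and transient timing is preserved.
    """
    nyquist = segment.sample_rate / 2
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff_hz}")
    sos = signal.butter(order, cutoff_hz, btype="highpass",
                        fs=segment.sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, segment.samples)
    return AudioSegment(filtered, segment.sample_rate, segment.start_time)


def mix_signals(a: AudioSegment, b: AudioSegment, gain_a: float = 1.0,
                gain_b: float = 1.0) -> AudioSegment:
    """Sample-wise weighted sum of two segments, peak-normalized if it clips.

    Segments must share a sample rate; the longer one is cropped to the
    shorter. Useful for building leak + heart + background mixtures.
    """
    if a.sample_rate != b.sample_rate:
        raise ValueError(
            f"sample-rate mismatch: {a.sample_rate} vs {b.sample_rate} Hz")
    n = min(a.samples.size, b.samples.size)
    mixed = gain_a * a.samples[:n] + gain_b * b.samples[:n]
    peak = float(np.max(np.abs(mixed))) if n else 0.0
    if peak > 1.0:
        mixed = mixed / peak
    return AudioSegment(mixed, a.sample_rate, a.start_time)


def power_density_histogram(spectrum: PowerSpectrum,
                            bin_db: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of spectral power values in fixed-width dB bins.

    Returns ``(bin_edges_db, counts)``; counts sum to the number of frequency
    bins. Comparing this histogram before and after high-pass filtering shows
    the removed low-frequency (heart-sound) mass.
    """
    if not bin_db > 0:
        raise ValueError("bin_db must be positive")
    if spectrum.power.size == 0:
        raise ValueError("empty spectrum")
    lo = np.floor(spectrum.power.min() / bin_db) * bin_db
    hi = np.ceil(spectrum.power.max() / bin_db) * bin_db
    if hi <= lo:
        hi = lo + bin_db
    edges = np.arange(lo, hi + bin_db / 2, bin_db)
    counts, _ = np.histogram(spectrum.power, bins=edges)
    return edges, counts
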