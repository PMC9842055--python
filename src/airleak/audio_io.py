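"""Audio and airway-pressure I/O.

All downstream analysis consumes two in-memory containers: :class:`AudioSegment`
(a mono waveform with sample rate, nominal amplitude range -1..+1) and
:class:`PressureTrace` (airway pressure in cmH2O versus time in seconds).
WAV files are RIFF PCM16/PCM24/float32 mono; pressure traces are CSV with
header columns ``time_s, pressure_cmH2O``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioSegment",
    "PressureTrace",
    "read_wav",
    "write_wav",
    "read_pressure_csv",
    "write_pressure_csv",
    "resample",
]


@dataclass
class AudioSegment:
    """Uniformly sampled mono waveform.

    Parameters
    ----------
    samples
        Amplitude sequence, dimensionless, nominal range -1..+1 (full scale).
    sample_rate
        Sampling rate in Hz.
    start_time
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSegment requires a 1-D (mono) sample array")
        if self.samples.size < 1:
            raise ValueError("AudioSegment requires at least one sample")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioSegment samples must all be finite")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.samples.size) / self.sample_rate

    def crop(self, t0: float, t1: float) -> "AudioSegment":
        """Return the sub-segment with times in [t0, t1)."""
        if not t0 < t1:
            raise ValueError(f"empty crop window [{t0}, {t1})")
        i0 = max(0, math.ceil((t0 - self.start_time) * self.sample_rate - 1e-9))
        i1 = min(self.samples.size, math.ceil((t1 - self.start_time) * self.sample_rate))
        if i1 <= i0:
            raise ValueError(f"crop window [{t0}, {t1}) contains no samples")
        return AudioSegment(self.samples[i0:i1], self.sample_rate,
                            self.start_time + i0 / self.sample_rate)


@dataclass
class PressureTrace:
    """Airway pressure versus time.

    ``ambient_pressure`` is the reference (intrapleural/atmospheric) pressure;
    the driving pressure difference is ``delta_p = max(pressure) - ambient``.
    """

    times: np.ndarray
    pressure: np.ndarray
    ambient_pressure: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.pressure = np.asarray(self.pressure, dtype=np.float64)
        if self.times.shape != self.pressure.shape or self.times.ndim != 1:
            raise ValueError("times and pressure must be 1-D arrays of equal length")
        if self.times.size < 1:
            raise ValueError("PressureTrace requires at least one sample")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.pressure))):
            raise ValueError("PressureTrace values must all be finite")

    @property
    def peak_pressure(self) -> float:
        """Maximum pressure (peak inspiratory pressure over the trace), cmH2O."""
        return float(np.max(self.pressure))

    @property
    def delta_p(self) -> float:
        """Driving pressure difference: max(pressure) - ambient_pressure, cmH2O."""
        return self.peak_pressure - self.ambient_pressure


_INT_FULL_SCALE = {np.dtype(np.int16): 2 ** 15, np.dtype(np.int32): 2 ** 31}


def read_wav(path, allow_multichannel: bool = False) -> AudioSegment:
    """Read a mono WAV file into an :class:`AudioSegment`.

    Integer PCM samples are normalized by their full-scale value; float files
    are taken as already in -1..+1. Multi-channel files are rejected unless
    ``allow_multichannel`` is set, in which case channels are averaged.
    """
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        if not allow_multichannel:
            raise ValueError(
                f"{path}: {data.shape[1]}-channel file; pass allow_multichannel=True "
                "to average channels")
        data = data.mean(axis=1)
    if data.dtype.kind == "i":
        # 24-bit PCM arrives as int32 with the low byte zero; full-scale 2^31 still applies
        samples = data.astype(np.float64) / _INT_FULL_SCALE[data.dtype]
    elif data.dtype.kind == "u":  # uint8 PCM is offset-binary
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    return AudioSegment(samples, float(rate), start_time=0.0)


def write_wav(segment: AudioSegment, path, subtype: str = "float32",
              clip: bool = False) -> None:
    """Write an :class:`AudioSegment` as a WAV file (``float32`` or ``pcm16``).

    Samples outside -1..+1 raise unless ``clip`` is set, in which case they are
    clipped to full scale.
    """
    samples = segment.samples
    peak = float(np.max(np.abs(samples))) if samples.size else 0.0
    if peak > 1.0:
        if not clip:
            raise ValueError(
                f"samples exceed full scale (peak {peak:.4g}); pass clip=True to clip")
        samples = np.clip(samples, -1.0, 1.0)
    if subtype == "float32":
        wavfile.write(path, int(round(segment.sample_rate)), samples.astype(np.float32))
    elif subtype == "pcm16":
        quantized = np.clip(np.round(samples * 2 ** 15), -(2 ** 15),
                            2 ** 15 - 1).astype(np.int16)
        wavfile.write(path, int(round(segment.sample_rate)), quantized)
    else:
        raise ValueError(f"unsupported subtype {subtype!r}; use 'float32' or 'pcm16'")


def read_pressure_csv(path) -> PressureTrace:
    """Read an airway-pressure trace from CSV with columns time_s, pressure_cmH2O."""
    frame = pd.read_csv(path)
    missing = {"time_s", "pressure_cmH2O"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    for col in ("time_s", "pressure_cmH2O"):
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(values.isna() & frame[col].notna())
        if frame[col].isna().any() or bad.size:
            row = int(bad[0]) if bad.size else int(np.flatnonzero(frame[col].isna())[0])
            raise ValueError(f"{path}: non-numeric or missing value in {col}, row {row}")
        frame[col] = values
    times = frame["time_s"].to_numpy(dtype=np.float64)
    if not np.all(np.diff(times) > 0):
        row = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
        raise ValueError(f"{path}: time_s not strictly increasing at row {row}")
    return PressureTrace(times, frame["pressure_cmH2O"].to_numpy(dtype=np.float64))


def write_pressure_csv(trace: PressureTrace, path) -> None:
    """Write a pressure trace as CSV (time_s, pressure_cmH2O)."""
    pd.DataFrame({"time_s": trace.times, "pressure_cmH2O": trace.pressure}).to_csv(
        path, index=False)


def resample(segment: AudioSegment, target_rate: float) -> AudioSegment:
    """Band-limited resampling to ``target_rate`` Hz (polyphase)."""
    if not target_rate > 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == segment.sample_rate:
        return AudioSegment(segment.samples.copy(), segment.sample_rate,
                            segment.start_time)
    up = int(round(target_rate * 1000))
    down = int(round(segment.sample_rate * 1000))
    g = math.gcd(up, down)
    # kaiser beta 8.6 keeps passband ripple well below 1e-3
    resampled = resample_poly(segment.samples, up // g, down // g,
                              window=("kaiser", 8.6))
    return AudioSegment(resampled, target_rate, segment.start_time)
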