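"""Seeded generator of ground-truthed acoustic leak scenes.

The generative model follows the physics of a free-flowing pleural air leak
under positive-pressure ventilation: escaping air transfers kinetic energy to
the pleural tissue, which oscillates at its resonance and overtones. The leak
component is therefore a harmonic series whose band powers fall linearly with
frequency (configurable slope/intercept in dB per Hz), amplitude-modulated by
the airway pressure. A ventilator can add a stationary tone that is *not* part
of the series — the classic distractor that band-exclusion logic must reject.
Heart sounds are S1/S2 Gaussian tone bursts confined below 400 Hz, and the
ambient is seeded Gaussian noise. Every scene carries a :class:`SceneTruth`
sufficient to score each downstream estimator.

Two presets mirror the reference study conditions: a small-rodent regime
(70 breaths/min, 16.2 cmH2O peak, fundamental 1223 Hz with harmonics
{1,2,3,4,5,7} plus an 890 Hz ventilator tone) and a human-sized swine regime
(15 breaths/min, PEEP 5 cmH2O, fundamental 665 Hz with harmonics {1,2,3,4}).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioSegment, PressureTrace

__all__ = [
    "VentConfig",
    "LeakConfig",
    "HeartConfig",
    "SceneConfig",
    "SceneTruth",
    "rat_config",
    "swine_config",
    "gen_pressure",
    "gen_leak_sound",
    "gen_heart_sound",
    "gen_scene",
    "gen_grid_recordings",
]

HEART_MAX_HZ = 400.0


@dataclass
class VentConfig:
    """Positive-pressure ventilation waveform parameters."""

    bpm: float = 15.0              # breaths per minute
    pip: float = 25.2              # peak inspiratory pressure, cmH2O
    peep: float = 5.0              # positive end-expiratory pressure, cmH2O
    rise_fraction: float = 0.3     # fraction of the breath spent inflating
    plateau_fraction: float = 0.2  # fraction held at PIP


@dataclass
class LeakConfig:
    """Harmonic leak source: band k sits at k*fundamental with peak power
    slope*f + intercept (dB re full scale) at the inspiratory plateau."""

    fundamental_hz: float = 665.0
    harmonic_numbers: tuple[int, ...] = (1, 2, 3, 4)
    power_slope_db_per_hz: float = -0.00792
    power_intercept_db: float = -34.8
    pressure_exponent: float = 1.0
    strength: float = 1.0


@dataclass
class HeartConfig:
    """S1/S2 heart-sound bursts; all spectral content must stay below 400 Hz."""

    bpm: float = 60.0
    s1_hz: float = 90.0
    s2_hz: float = 120.0
    s2_delay_s: float = 0.32
    burst_duration_s: float = 0.08
    level_db: float = -30.0


@dataclass
class SceneConfig:
    sample_rate: float = 44_100.0
    duration_s: float = 10.0
    vent: VentConfig = field(default_factory=VentConfig)
    leak: LeakConfig = field(default_factory=LeakConfig)
    extra_tones: tuple[tuple[float, float], ...] = ()  # (Hz, dB re full scale)
    heart: HeartConfig | None = None
    ambient_level_db: float = -60.0  # RMS, dB re full scale
    pressure_rate_hz: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        nyquist = self.sample_rate / 2
        if not self.vent.pip > self.vent.peep:
            raise ValueError("PIP must exceed PEEP")
        if self.vent.rise_fraction + self.vent.plateau_fraction > 1:
            raise ValueError("rise + plateau fractions must not exceed 1")
        top = max(self.leak.harmonic_numbers) * self.leak.fundamental_hz
        if top >= nyquist:
            raise ValueError(
                f"harmonic at {top} Hz at or above Nyquist ({nyquist} Hz)")
        if any(f >= nyquist for f, _ in self.extra_tones):
            raise ValueError("extra tone at or above Nyquist")
        if list(self.leak.harmonic_numbers) != sorted(set(self.leak.harmonic_numbers)) \
                or min(self.leak.harmonic_numbers) < 1:
            raise ValueError("harmonic_numbers must be strictly increasing positives")
        if self.heart is not None:
            if max(self.heart.s1_hz, self.heart.s2_hz) > 200.0:
                raise ValueError("heart burst centers must be <= 200 Hz")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SceneConfig":
        data = dict(data)
        if "vent" in data:
            data["vent"] = VentConfig(**data["vent"])
        if "leak" in data:
            leak = dict(data["leak"])
            leak["harmonic_numbers"] = tuple(leak.get("harmonic_numbers", (1, 2, 3, 4)))
            data["leak"] = LeakConfig(**leak)
        if data.get("heart") is not None:
            data["heart"] = HeartConfig(**data["heart"])
        if "extra_tones" in data:
            data["extra_tones"] = tuple((float(f), float(l))
                                        for f, l in data["extra_tones"])
        return cls(**data)


@dataclass
class SceneTruth:
    """Ground truth recorded alongside each generated scene."""

    pressure: PressureTrace
    fundamental_hz: float
    harmonic_numbers: tuple[int, ...]
    component_gains: dict
    seed: int
    leak_cell: tuple[int, int] | None = None
    leak_position_cm: tuple[float, float] | None = None


def rat_config(**overrides) -> SceneConfig:
    """Small-rodent preset: 70 bpm, 16.2/2.1 cmH2O, f0 1223 Hz, harmonics
    {1,2,3,4,5,7}, 890 Hz ventilator tone, band-power line -0.00231f - 49.1."""
    cfg = SceneConfig(
        vent=VentConfig(bpm=70.0, pip=16.2, peep=2.1),
        leak=LeakConfig(fundamental_hz=1223.0, harmonic_numbers=(1, 2, 3, 4, 5, 7),
                        power_slope_db_per_hz=-0.00231, power_intercept_db=-49.1),
        extra_tones=((890.0, -45.0),),
    )
    return dataclasses.replace(cfg, **overrides)


def swine_config(**overrides) -> SceneConfig:
    """Human-sized swine preset: 15 bpm, PEEP 5 cmH2O, f0 665 Hz, harmonics
    {1,2,3,4}, band-power line -0.00792f - 34.8."""
    cfg = SceneConfig(duration_s=20.0)
    return dataclasses.replace(cfg, **overrides)


def gen_pressure(config: SceneConfig) -> PressureTrace:
    """Periodic ventilation waveform: linear rise to PIP, plateau hold,
    exponential decay back to PEEP (reaching PEEP exactly at breath end)."""
    config.validate()
    vent = config.vent
    period = 60.0 / vent.bpm
    times = np.arange(0.0, config.duration_s, 1.0 / config.pressure_rate_hz)
    phase = np.mod(times, period) / period  # 0..1 within each breath
    rise, plateau = vent.rise_fraction, vent.plateau_fraction
    p = np.empty_like(times)
    span = vent.pip - vent.peep

    in_rise = phase < rise
    p[in_rise] = vent.peep + span * phase[in_rise] / rise
    in_plateau = (phase >= rise) & (phase < rise + plateau)
    p[in_plateau] = vent.pip
    in_decay = phase >= rise + plateau
    decay_len = 1.0 - rise - plateau
    tau = decay_len / 4.0
    u = (phase[in_decay] - rise - plateau) / 1.0  # breath fraction into decay
    # normalized so pressure hits PEEP exactly at the end of the breath
    e_end = np.exp(-decay_len / tau)
    p[in_decay] = vent.peep + span * (np.exp(-u / tau) - e_end) / (1.0 - e_end)
    return PressureTrace(times, p)


def _band_amplitude(level_db: float) -> float:
    # welch 'spectrum' scaling puts a sine of amplitude a at peak power a^2/2
    return np.sqrt(2.0) * 10.0 ** (level_db / 20.0)


def _pressure_envelope(config: SceneConfig, pressure: PressureTrace,
                       n: int) -> np.ndarray:
    t_audio = np.arange(n) / config.sample_rate
    p = np.interp(t_audio, pressure.times, pressure.pressure)
    drive = np.maximum(0.0, p - pressure.ambient_pressure)
    peak = config.vent.pip - pressure.ambient_pressure
    if peak <= 0:
        return np.zeros(n)
    return config.leak.strength * (drive / peak) ** config.leak.pressure_exponent


def gen_leak_sound(config: SceneConfig, pressure: PressureTrace,
                   rng: np.random.Generator | None = None) -> AudioSegment:
    """Harmonic leak source amplitude-modulated by airway pressure.

    Each harmonic k contributes a sine at k*f0 with seeded phase; amplitudes
    are set so the plateau power spectrum shows band peaks on the configured
    power line. The whole sum is scaled by
    ``strength * ((P(t) - ambient)/ (PIP - ambient))^exponent``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    carrier = np.zeros(n)
    for k in config.leak.harmonic_numbers:
        f = k * config.leak.fundamental_hz
        level = (config.leak.power_slope_db_per_hz * f
                 + config.leak.power_intercept_db)
        phi = rng.uniform(0, 2 * np.pi)
        carrier += _band_amplitude(level) * np.sin(2 * np.pi * f * t + phi)
    envelope = _pressure_envelope(config, pressure, n)
    return AudioSegment(carrier * envelope, config.sample_rate)


def gen_heart_sound(config: SceneConfig) -> AudioSegment:
    """S1/S2 heart sounds: per beat, two Gaussian-windowed tone bursts.

    The Gaussian time window keeps the spectrum Gaussian too; with default
    centers (90/120 Hz) and burst width, at least 99% of spectral power lies
    below 400 Hz, which the generator verifies before returning.
    """
    config.validate()
    if config.heart is None:
        raise ValueError("scene config has no heart component")
    h = config.heart
    n = int(round(config.duration_s * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    x = np.zeros(n)
    amp = 10.0 ** (h.level_db / 20.0)
    if amp > 0:
        sigma = h.burst_duration_s / 6.0
        period = 60.0 / h.bpm
        n_beats = int(np.ceil(config.duration_s / period))
        for i in range(n_beats):
            t_beat = i * period + h.burst_duration_s
            for f, t_c in ((h.s1_hz, t_beat), (h.s2_hz, t_beat + h.s2_delay_s)):
                envelope = np.exp(-0.5 * ((t - t_c) / sigma) ** 2)
                x += amp * envelope * np.sin(2 * np.pi * f * (t - t_c))
        spectrum = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(n, d=1.0 / config.sample_rate)
        below = spectrum[freqs < HEART_MAX_HZ].sum()
        if below < 0.99 * spectrum.sum():
            raise ValueError(
                "heart configuration leaks >1% of spectral power above 400 Hz")
    return AudioSegment(x, config.sample_rate)


def gen_scene(config: SceneConfig) -> tuple[AudioSegment, SceneTruth]:
    """Full acoustic scene: leak + ventilator tones + heart + ambient noise.

    Deterministic: the same config and seed produce bit-identical audio.
    If the mixture would clip, it is peak-normalized and the applied gain
    recorded in the truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pressure = gen_pressure(config)
    leak = gen_leak_sound(config, pressure, rng=rng)
    n = leak.samples.size
    t = np.arange(n) / config.sample_rate
    mix = leak.samples.copy()
    for f, level in config.extra_tones:
        phi = rng.uniform(0, 2 * np.pi)
        mix += _band_amplitude(level) * np.sin(2 * np.pi * f * t + phi)
    if config.heart is not None:
        mix += gen_heart_sound(config).samples
    if config.ambient_level_db > -np.inf:
        noise_rms = 10.0 ** (config.ambient_level_db / 20.0)
        mix += noise_rms * rng.standard_normal(n)
    gain = 1.0
    peak = float(np.max(np.abs(mix)))
    if peak > 1.0:
        gain = 1.0 / peak
        mix *= gain
    truth = SceneTruth(pressure=pressure,
                       fundamental_hz=config.leak.fundamental_hz,
                       harmonic_numbers=tuple(config.leak.harmonic_numbers),
                       component_gains={"master": gain,
                                        "leak_strength": config.leak.strength,
                                        "ambient_level_db": config.ambient_level_db},
                       seed=config.seed)
    return AudioSegment(mix, config.sample_rate), truth


def gen_grid_recordings(config: SceneConfig, n_rows: int, n_cols: int,
                        step_cm: float = 1.0,
                        leak_cell: tuple[int, int] | None = (2, 2),
                        standoff_cm: float = 1.0, snr_db: float = 10.0,
                        ) -> tuple[list[tuple[tuple[int, int], AudioSegment]],
                                   SceneTruth]:
    """Per-cell grid recordings with inverse-distance leak attenuation.

    The leak sits at the center of ``leak_cell``; the microphone at each cell
    hovers ``standoff_cm`` above its center, so the source-microphone distance
    is ``r = sqrt(lateral^2 + standoff^2)`` and the leak amplitude scales as
    ``standoff / r`` (spherical spreading with a near-field floor at the
    standoff). Each cell receives independent seeded Gaussian ambient noise at
    ``snr_db`` relative to the leak RMS at the loudest (source) cell.
    ``leak_cell=None`` produces an ambient-only (uninjured) grid.
    """
    config.validate()
    if leak_cell is not None and not (
            0 <= leak_cell[0] < n_rows and 0 <= leak_cell[1] < n_cols):
        raise ValueError(f"leak_cell {leak_cell} outside {n_rows}x{n_cols} grid")
    seq = np.random.SeedSequence(config.seed)
    child_seeds = seq.spawn(n_rows * n_cols + 1)
    pressure = gen_pressure(config)
    leak = gen_leak_sound(config, pressure,
                          rng=np.random.default_rng(child_seeds[0]))
    source_rms = float(np.sqrt(np.mean(leak.samples ** 2)))
    noise_rms = source_rms * 10.0 ** (-snr_db / 20.0) if leak_cell is not None \
        else 10.0 ** (config.ambient_level_db / 20.0)

    recordings = []
    for r in range(n_rows):
        for c in range(n_cols):
            rng = np.random.default_rng(child_seeds[1 + r * n_cols + c])
            noise = noise_rms * rng.standard_normal(leak.samples.size)
            if leak_cell is None:
                samples = noise
            else:
                lateral = step_cm * np.hypot(r - leak_cell[0], c - leak_cell[1])
                dist = np.hypot(lateral, standoff_cm)
                samples = leak.samples * (standoff_cm / dist) + noise
            recordings.append(((r, c), AudioSegment(samples, config.sample_rate)))

    position = (None if leak_cell is None
                else (leak_cell[1] * step_cm, leak_cell[0] * step_cm))
    truth = SceneTruth(pressure=pressure,
                       fundamental_hz=config.leak.fundamental_hz,
                       harmonic_numbers=tuple(config.leak.harmonic_numbers),
                       component_gains={"snr_db": snr_db,
                                        "standoff_cm": standoff_cm},
                       seed=config.seed, leak_cell=leak_cell,
                       leak_position_cm=position)
    return recordings, truth
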