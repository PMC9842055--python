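import dataclasses

import numpy as np
import pytest

import airleak as al


def make_tone(freq_hz: float, duration_s: float = 1.0, amplitude: float = 1.0,
              sample_rate: float = 44_100.0) -> al.AudioSegment:
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    return al.AudioSegment(amplitude * np.sin(2 * np.pi * freq_hz * t),
                           sample_rate)


@pytest.fixture
def tone():
    return make_tone


@pytest.fixture(scope="session")
def rat_scene():
    """10 s small-rodent scene with ground truth (seeded)."""
    config = al.rat_config(seed=11)
    audio, truth = al.gen_scene(config)
    return config, audio, truth


@pytest.fixture(scope="session")
def swine_scene():
    """20 s human-sized-lung scene with ground truth (seeded)."""
    config = al.swine_config(seed=12)
    audio, truth = al.gen_scene(config)
    return config, audio, truth


@pytest.fixture(scope="session")
def swine_plateau_spectrum(swine_scene):
    _, audio, truth = swine_scene
    seg = al.detect_breaths(truth.pressure)
    best = int(np.argmax(seg.peak_pressures))
    t0, t1 = seg.plateau_windows[best]
    return al.power_spectrum(audio, t0, t1)


@pytest.fixture
def heart_config():
    return dataclasses.replace(al.swine_config(seed=13, duration_s=10.0),
                               heart=al.HeartConfig())
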