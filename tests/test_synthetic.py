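import dataclasses

import numpy as np
import pytest
from scipy.signal import find_peaks

import airleak as al


class TestGenPressure:
    def test_swine_minima_at_peep(self):
        trace = al.gen_pressure(al.swine_config(duration_s=20.0))
        assert trace.pressure.min() == pytest.approx(5.0, abs=0.01)
        assert trace.pressure.max() == pytest.approx(25.2, abs=0.01)

    def test_rat_peak_count(self):
        trace = al.gen_pressure(al.rat_config(duration_s=10.0))
        peaks, _ = find_peaks(trace.pressure, prominence=2.0)
        assert peaks.size in (11, 12)

    def test_triangular_degenerate_plateau(self):
        cfg = al.swine_config(duration_s=20.0)
        cfg = dataclasses.replace(
            cfg, vent=dataclasses.replace(cfg.vent, plateau_fraction=0.0))
        trace = al.gen_pressure(cfg)
        seg = al.detect_breaths(trace)
        period = 60.0 / cfg.vent.bpm
        # no pressure hold: the 90%-of-peak plateau degenerates to a sliver
        # of the breath instead of the configured 20% hold
        for t0, t1 in seg.plateau_windows:
            assert t1 - t0 <= 0.1 * period

    def test_pip_not_above_peep_rejected(self):
        cfg = al.swine_config()
        cfg = dataclasses.replace(
            cfg, vent=dataclasses.replace(cfg.vent, pip=5.0, peep=5.0))
        with pytest.raises(ValueError, match="PIP"):
            al.gen_pressure(cfg)


class TestGenLeakSound:
    def test_ambient_pressure_produces_silence(self):
        cfg = al.swine_config(duration_s=2.0)
        times = np.arange(0, 2.0, 0.01)
        flat = al.PressureTrace(times, np.zeros(times.size))
        out = al.gen_leak_sound(cfg, flat)
        assert np.all(out.samples == 0.0)

    def test_harmonic_above_nyquist_rejected(self):
        cfg = al.swine_config(sample_rate=4000.0)
        with pytest.raises(ValueError, match="Nyquist"):
            al.gen_leak_sound(cfg, al.gen_pressure(cfg))

    @pytest.mark.parametrize("config_fn", [al.rat_config, al.swine_config])
    def test_plateau_band_powers_on_configured_line(self, config_fn):
        cfg = config_fn(seed=31, duration_s=10.0)
        pressure = al.gen_pressure(cfg)
        leak = al.gen_leak_sound(cfg, pressure,
                                 rng=np.random.default_rng(31))
        seg = al.detect_breaths(pressure)
        t0, t1 = seg.plateau_windows[int(np.argmax(seg.peak_pressures))]
        spec = al.power_spectrum(leak, t0, t1)
        found = al.detect_bands(spec, -85.0, 200.0, fmin=400, fmax=11_000)
        assert len(found) == len(cfg.leak.harmonic_numbers)
        for band in found:
            expected = (cfg.leak.power_slope_db_per_hz * band.center_hz
                        + cfg.leak.power_intercept_db)
            assert band.peak_power_db == pytest.approx(expected, abs=1.0)
        fit = al.band_power_regression(found)
        assert fit.slope == pytest.approx(cfg.leak.power_slope_db_per_hz,
                                          rel=0.10)
        assert fit.intercept == pytest.approx(cfg.leak.power_intercept_db,
                                              abs=1.0)


class TestGenHeartSound:
    def test_beat_pair_count(self, heart_config):
        heart = al.gen_heart_sound(heart_config)
        envelope = np.abs(heart.samples)
        # smooth the envelope and count bursts: 10 s at 60 bpm -> 10 S1-S2 pairs
        kernel = np.ones(int(0.05 * heart.sample_rate))
        smooth = np.convolve(envelope, kernel / kernel.sum(), mode="same")
        bursts, _ = find_peaks(smooth, height=0.3 * smooth.max(),
                               distance=int(0.15 * heart.sample_rate))
        assert bursts.size == 2 * 10

    def test_spectral_content_below_400(self, heart_config):
        heart = al.gen_heart_sound(heart_config)
        spec = al.power_spectrum(heart)
        peak = spec.power.max()
        loud = spec.frequencies[spec.power > peak - 60.0]
        assert loud.max() <= 400.0

    def test_zero_level_is_silence(self, heart_config):
        cfg = dataclasses.replace(
            heart_config,
            heart=dataclasses.replace(heart_config.heart, level_db=-np.inf))
        heart = al.gen_heart_sound(cfg)
        assert np.all(heart.samples == 0.0)

    def test_center_above_limit_rejected(self, heart_config):
        cfg = dataclasses.replace(
            heart_config,
            heart=dataclasses.replace(heart_config.heart, s2_hz=350.0))
        with pytest.raises(ValueError, match="200"):
            al.gen_heart_sound(cfg)


class TestGenScene:
    def test_seed_determinism_bit_identical(self):
        cfg = al.swine_config(seed=17, duration_s=4.0)
        a, _ = al.gen_scene(cfg)
        b, _ = al.gen_scene(cfg)
        assert a.samples.tobytes() == b.samples.tobytes()

    def test_different_seeds_differ(self):
        a, _ = al.gen_scene(al.swine_config(seed=1, duration_s=2.0))
        b, _ = al.gen_scene(al.swine_config(seed=2, duration_s=2.0))
        assert not np.array_equal(a.samples, b.samples)

    def test_silent_heart_equals_no_heart(self):
        base = al.swine_config(seed=19, duration_s=3.0)
        silent_heart = dataclasses.replace(
            base, heart=al.HeartConfig(level_db=-np.inf))
        a, _ = al.gen_scene(base)
        b, _ = al.gen_scene(silent_heart)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_end_to_end_fundamental_recovery(self, swine_scene):
        _, audio, truth = swine_scene
        seg = al.detect_breaths(truth.pressure)
        t0, t1 = seg.plateau_windows[int(np.argmax(seg.peak_pressures))]
        spec = al.power_spectrum(audio, t0, t1)
        found = al.detect_bands(spec, -60.0, 200.0, fmin=400, fmax=5000)
        series = al.find_harmonic_series(found)
        df = spec.frequencies[1] - spec.frequencies[0]
        assert series.fundamental_hz == pytest.approx(truth.fundamental_hz,
                                                      abs=4 * df)


class TestGridRecordings:
    def test_noise_free_maximum_at_leak_cell(self):
        cfg = al.swine_config(seed=23, sample_rate=16_000.0, duration_s=5.0)
        recordings, truth = al.gen_grid_recordings(cfg, 5, 5, leak_cell=(2, 2),
                                                   snr_db=300.0)
        matrix = al.build_matrix(recordings, 5, 5)
        best = np.unravel_index(np.argmax(matrix.raw_dba),
                                matrix.raw_dba.shape)
        assert tuple(best) == truth.leak_cell

    def test_attenuation_follows_inverse_distance(self):
        cfg = al.swine_config(seed=24, sample_rate=16_000.0, duration_s=5.0)
        recordings, _ = al.gen_grid_recordings(cfg, 3, 3, leak_cell=(0, 0),
                                               snr_db=300.0, standoff_cm=1.0)
        by_cell = dict(recordings)
        rms = {cell: np.sqrt(np.mean(seg.samples ** 2))
               for cell, seg in by_cell.items()}
        # cell (0,2): lateral 2 cm, r = sqrt(5); source r = 1
        expected_ratio = 1.0 / np.sqrt(5.0)
        assert rms[(0, 2)] / rms[(0, 0)] == pytest.approx(expected_ratio,
                                                          rel=1e-3)

    def test_leak_cell_outside_grid_rejected(self):
        cfg = al.swine_config(sample_rate=16_000.0, duration_s=1.0)
        with pytest.raises(ValueError, match="outside"):
            al.gen_grid_recordings(cfg, 3, 3, leak_cell=(5, 0))

    def test_grid_determinism(self):
        cfg = al.swine_config(seed=25, sample_rate=16_000.0, duration_s=1.0)
        a, _ = al.gen_grid_recordings(cfg, 2, 2, leak_cell=(0, 1))
        b, _ = al.gen_grid_recordings(cfg, 2, 2, leak_cell=(0, 1))
        for (cell_a, seg_a), (cell_b, seg_b) in zip(a, b):
            assert cell_a == cell_b
            assert seg_a.samples.tobytes() == seg_b.samples.tobytes()

    def test_localization_error_bounded_over_seeds(self):
        errors = []
        for seed in range(20):
            cfg = al.swine_config(seed=seed, sample_rate=16_000.0,
                                  duration_s=5.0)
            recordings, truth = al.gen_grid_recordings(
                cfg, 5, 5, leak_cell=(2, 2), snr_db=10.0)
            matrix = al.normalize_matrix(al.build_matrix(recordings, 5, 5))
            loc = al.locate_leak(matrix)
            errors.append(al.localization_error(loc, truth.leak_position_cm))
        assert max(errors) <= 1.0
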