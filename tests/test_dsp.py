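import numpy as np
import pytest

import airleak as al
from airleak.dsp import SPL_FLOOR_DB


def rms_db(x):
    return 20.0 * np.log10(np.sqrt(np.mean(np.asarray(x) ** 2)))


class TestAWeighting:
    @pytest.mark.parametrize("freq,expected,tol", [
        (1000.0, 0.0, 0.01),      # normalization point of the A-curve
        (100.0, -19.1, 0.1),      # closed-form value at 100 Hz
        (10_000.0, -2.5, 0.1),    # closed-form value at 10 kHz
    ])
    def test_reference_points(self, freq, expected, tol):
        assert al.a_weighting_gain(freq) == pytest.approx(expected, abs=tol)

    def test_curve_unimodal_with_peak_near_2500(self):
        freqs = np.logspace(1, 4.3, 400)
        gains = al.a_weighting_gain(freqs)
        peak = freqs[np.argmax(gains)]
        assert 2000 < peak < 3000
        ipeak = int(np.argmax(gains))
        assert np.all(np.diff(gains[:ipeak + 1]) > 0)
        assert np.all(np.diff(gains[ipeak:]) < 0)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            al.a_weighting_gain(0.0)

    @pytest.mark.parametrize("freq", [100.0, 1000.0, 5000.0])
    def test_filter_matches_curve_on_tones(self, tone, freq):
        seg = tone(freq, 1.0, amplitude=0.5)
        out = al.apply_a_weighting(seg)
        measured = rms_db(out.samples) - rms_db(seg.samples)
        assert measured == pytest.approx(al.a_weighting_gain(freq), abs=0.5)

    def test_zero_signal_maps_to_zero(self):
        seg = al.AudioSegment(np.zeros(1000), 8000.0)
        out = al.apply_a_weighting(seg)
        assert np.allclose(out.samples, 0.0, atol=1e-15)


class TestSplSeries:
    def test_full_scale_sine_level(self, tone):
        # full-scale 1 kHz sine: RMS = 1/sqrt(2) -> 94 - 3.01 dB
        seg = tone(1000.0, 2.0)
        series = al.spl_series(seg, calibration_offset=94.0)
        assert np.median(series.level) == pytest.approx(94.0 - 3.0103, abs=0.05)

    def test_matches_brute_force_oracle(self, tone):
        seg = tone(800.0, 1.0, amplitude=0.3)
        window_s, hop_s = 0.125, 0.03125
        series = al.spl_series(seg, window_s, hop_s, calibration_offset=94.0)
        weighted = al.apply_a_weighting(seg).samples
        nwin = int(round(window_s * seg.sample_rate))
        nhop = int(round(hop_s * seg.sample_rate))
        expected = []
        for start in range(0, weighted.size - nwin + 1, nhop):
            w = weighted[start:start + nwin]
            expected.append(20 * np.log10(np.sqrt(np.mean(w ** 2))) + 94.0)
        np.testing.assert_allclose(series.level, expected, atol=1e-9)

    def test_doubling_amplitude_adds_6db(self, tone):
        a = tone(700.0, 1.0, amplitude=0.25)
        b = al.AudioSegment(2 * a.samples, a.sample_rate)
        la = al.spl_series(a).level
        lb = al.spl_series(b).level
        np.testing.assert_allclose(lb - la, 20 * np.log10(2), atol=1e-9)

    def test_short_segment_rejected(self, tone):
        with pytest.raises(ValueError, match="shorter"):
            al.spl_series(tone(1000.0, 0.05), window_s=0.125)


class TestSpectrogram:
    def test_pure_tone_single_ridge(self, tone):
        seg = tone(1223.0, 1.0)
        spec = al.spectrogram(seg)
        df = spec.frequencies[1] - spec.frequencies[0]
        for row in spec.power:
            assert abs(spec.frequencies[np.argmax(row)] - 1223.0) <= df

    def test_zero_signal_hits_floor(self):
        seg = al.AudioSegment(np.zeros(44_100), 44_100.0)
        spec = al.spectrogram(seg, floor_db=-100.0)
        assert np.all(spec.power == -100.0)

    def test_two_tone_ridges_at_integer_ratio(self, tone):
        a = tone(665.0, 1.0, amplitude=0.4)
        b = tone(1330.0, 1.0, amplitude=0.4)
        spec = al.spectrogram(al.mix_signals(a, b))
        df = spec.frequencies[1] - spec.frequencies[0]
        mean_power = spec.power.mean(axis=0)
        order = np.argsort(mean_power)[::-1]
        top2 = sorted(spec.frequencies[order[:2]])
        assert abs(top2[0] - 665.0) <= df
        assert abs(top2[1] / top2[0] - 2.0) <= 2 * df / 665.0

    def test_stationary_tone_time_constant(self, tone):
        spec = al.spectrogram(tone(2000.0, 2.0, amplitude=0.5))
        ridge = spec.power.max(axis=1)[1:-1]  # skip edge windows
        assert np.ptp(ridge) <= 1.0

    def test_window_longer_than_signal_rejected(self, tone):
        with pytest.raises(ValueError):
            al.spectrogram(tone(500.0, 0.05), window_s=0.2)


class TestPowerSpectrum:
    def test_tone_peak_within_one_bin(self, tone):
        spec = al.power_spectrum(tone(5020.0, 1.0))
        df = spec.frequencies[1] - spec.frequencies[0]
        # oversampled grid: peak must land within the unpadded bin width
        assert abs(spec.frequencies[np.argmax(spec.power)] - 5020.0) <= 4 * df

    def test_seeded_white_noise_flat(self):
        rng = np.random.default_rng(42)
        seg = al.AudioSegment(0.1 * rng.standard_normal(44_100 * 10), 44_100.0)
        spec = al.power_spectrum(seg)
        inner = spec.power[(spec.frequencies > 200)
                           & (spec.frequencies < 20_000)]
        assert np.ptp(inner) <= 6.0  # +-3 dB around the mean after averaging

    def test_zero_signal_uniform_floor(self):
        seg = al.AudioSegment(np.zeros(44_100), 44_100.0)
        spec = al.power_spectrum(seg)
        assert np.ptp(spec.power) == 0.0

    def test_empty_window_rejected(self, tone):
        with pytest.raises(ValueError):
            al.power_spectrum(tone(500.0, 1.0), 0.5, 0.5)


class TestHighpass:
    def test_stopband_tone_attenuated(self, tone):
        seg = tone(200.0, 1.0, amplitude=0.5)
        out = al.highpass(seg, 500.0, order=4)
        drop = rms_db(seg.samples[4410:-4410]) - rms_db(out.samples[4410:-4410])
        assert drop >= 30.0

    def test_passband_tone_preserved(self, tone):
        seg = tone(2000.0, 1.0, amplitude=0.5)
        out = al.highpass(seg, 500.0, order=4)
        drop = rms_db(seg.samples[4410:-4410]) - rms_db(out.samples[4410:-4410])
        assert abs(drop) <= 1.0

    def test_passivity_no_band_gains_energy(self, tone):
        rng = np.random.default_rng(3)
        seg = al.AudioSegment(0.2 * rng.standard_normal(44_100), 44_100.0)
        out = al.highpass(seg, 500.0)
        before = np.abs(np.fft.rfft(seg.samples)) ** 2
        after = np.abs(np.fft.rfft(out.samples)) ** 2
        # compare in coarse bands to avoid bin-level leakage artifacts
        for band in np.array_split(np.arange(before.size), 50):
            assert after[band].sum() <= before[band].sum() * 1.01

    def test_heart_removed_leak_bands_intact(self, swine_scene, heart_config):
        _, leak_audio, _ = swine_scene
        heart = al.gen_heart_sound(heart_config)
        mixed = al.mix_signals(leak_audio, heart)
        filtered = al.highpass(mixed, 500.0)
        freqs = np.fft.rfftfreq(mixed.samples.size, 1 / mixed.sample_rate)
        heart_in = np.abs(np.fft.rfft(heart.samples[:mixed.samples.size])) ** 2
        out_spec = np.abs(np.fft.rfft(filtered.samples)) ** 2
        low = freqs < 400.0
        assert out_spec[low].sum() <= 0.01 * heart_in[low].sum()
        spec = al.power_spectrum(filtered)
        detected = al.detect_bands(spec, -60.0, 200.0, fmin=500, fmax=5000)
        centers = sorted(b.center_hz for b in detected)
        assert centers[0] == pytest.approx(665.0, abs=10.0)

    def test_cutoff_at_nyquist_rejected(self, tone):
        with pytest.raises(ValueError):
            al.highpass(tone(500.0, 0.2), 22_050.0)


class TestMixAndHistogram:
    def test_mix_with_zeros_proportional(self, tone):
        a = tone(440.0, 0.5, amplitude=0.3)
        b = al.AudioSegment(np.zeros_like(a.samples), a.sample_rate)
        out = al.mix_signals(a, b, 2.0, 5.0)
        np.testing.assert_allclose(out.samples, 2.0 * a.samples, atol=1e-12)

    def test_identical_signals_double_then_normalize(self, tone):
        a = tone(440.0, 0.5, amplitude=0.8)
        out = al.mix_signals(a, a, 1.0, 1.0)
        # 1.6 peak would clip -> normalized back to 1.0
        assert np.max(np.abs(out.samples)) == pytest.approx(1.0)

    def test_rate_mismatch_rejected(self, tone):
        a = tone(440.0, 0.5)
        b = al.AudioSegment(np.zeros(100), 8000.0)
        with pytest.raises(ValueError, match="mismatch"):
            al.mix_signals(a, b)

    def test_uniform_spectrum_single_bin(self):
        spec = al.PowerSpectrum(np.arange(1.0, 100.0), np.full(99, -50.0),
                                (0.0, 1.0))
        _, counts = al.power_density_histogram(spec, bin_db=2.0)
        assert counts.sum() == 99
        assert np.count_nonzero(counts) == 1

    @pytest.mark.parametrize("bin_db", [0.5, 1.0, 3.0])
    def test_counts_conserved_under_bin_width(self, swine_plateau_spectrum,
                                              bin_db):
        _, counts = al.power_density_histogram(swine_plateau_spectrum, bin_db)
        assert counts.sum() == swine_plateau_spectrum.power.size

    def test_filtering_removes_low_frequency_mass(self, swine_scene,
                                                  heart_config):
        _, leak_audio, _ = swine_scene
        mixed = al.mix_signals(leak_audio, al.gen_heart_sound(heart_config))
        filtered = al.highpass(mixed, 500.0)
        spec_mixed = al.power_spectrum(mixed)
        spec_filt = al.power_spectrum(filtered)
        hi_power = -60.0
        n_loud_mixed = np.count_nonzero(spec_mixed.power > hi_power)
        n_loud_filt = np.count_nonzero(spec_filt.power > hi_power)
        assert n_loud_filt < n_loud_mixed

    def test_invalid_bin_width_rejected(self, swine_plateau_spectrum):
        with pytest.raises(ValueError):
            al.power_density_histogram(swine_plateau_spectrum, bin_db=0.0)
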