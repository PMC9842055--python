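# Methods

## Physical model and analysis chain

A free-flowing pulmonary air leak is driven by the pressure difference ΔP
between the airway and the pleural space. Escaping airflow transfers kinetic
energy to the tissue around the defect, which oscillates at its resonance and
overtones — the same mechanism as vocal-fold phonation. Two consequences
structure the whole package:

- the leak sound is a **harmonic series**: narrow spectral bands at integer
  multiples of a fundamental f₀ set by defect geometry (larger defects →
  lower f₀), with band power decreasing approximately linearly with frequency
  in dB;
- leak **loudness is modulated by airway pressure**: it rises during
  inspiration, peaks at the inspiratory plateau, and falls during expiration.

The analysis chain is: A-weighted SPL → breath segmentation from the pressure
trace → power spectrum of the inspiratory plateau → band detection →
harmonic-series identification → band-power regression → pressure–loudness
correlation → severity grading; independently, per-position mean loudness
over a microphone grid → normalized intensity matrix → leak localization.

## Levels and calibration

Recordings are uncalibrated digital waveforms, so all levels are **dB re
full scale** plus a configurable `calibration_offset` (default 94 dB,
the 1 kHz/94 dB SPL calibrator convention). Absolute dBA values therefore
depend on this offset; every relative quantity (band structure, regression
slope, correlation, normalized intensity, severity *ordering*) does not.

A-weighting uses the standard closed-form analog magnitude response
(pole frequencies 20.6, 107.7, 737.9, 12194 Hz), normalized to exactly
0 dB at 1 kHz. It is applied in the frequency domain: each rFFT bin is
scaled by the exact curve gain and the signal inverse-transformed. This is
zero-phase and matches the analytic curve to machine precision at every bin,
with no bilinear-warping error near 10 kHz; the cost is block (not
streaming) processing, which fits the offline-recording workflow.

SPL uses a 125 ms window and 31.25 ms hop (sound-level-meter "fast"
convention) over the A-weighted signal:
`L = 20·log10(RMS) + calibration_offset`, floored at −120 dB re full scale
for silent windows. Spectrograms use a Hann window of 4096 samples at
44.1 kHz (≈93 ms, ~10 Hz resolution — enough to separate 665 Hz
harmonics) with 50% overlap. Power spectra use Welch averaging with 4×
zero-padded FFTs so tone peak levels are read with <0.2 dB scalloping
error; a full-scale sine reads −3 dB (its mean square).

## Band and harmonic analysis

Bands are local spectral maxima above a threshold (−80 dB for the
small-rodent regime over 0–10 kHz; −60 dB for the swine regime over
0–5 kHz), merged within 200 Hz keeping the stronger peak. Band centers are
power-weighted centroids of the contiguous −3 dB neighborhood. The analysis
floor of 400 Hz in the pipeline presets skips the heart-sound region.

A band at frequency f is the k-th harmonic of f₀ when
`|f/f₀ − round(f/f₀)| ≤ 0.25`. The tolerance 0.25 is the smallest value
that accepts the observed ratios in both regimes (the largest printed
deviation is 8845/1223 = 7.23). The **fundamental is chosen by maximum
explained-band count**, not by loudness or lowest frequency: in the rodent
regime the loudest and lowest band (890 Hz) is ventilator noise and fits no
integer ratio, so it must be excludable. Ties go to the lower-frequency
candidate; duplicate harmonic numbers keep the smaller ratio residual;
harmonic numbers may skip integers (the rodent series lacks the 6th).
Band-power regression is ordinary least squares of peak power (dB) on center
frequency (Hz) with a two-sided p-value for zero slope; the zero-variance
(horizontal) case returns slope 0, R² 0 explicitly.

## Breath segmentation, correlation, severity

Inspiratory peaks are found by prominence (default 2 cmH₂O); breath
boundaries are the pressure minima around each peak. The **inspiratory
plateau** is the contiguous run of samples at ≥ 90% of that breath's peak
pressure — a reproducible surrogate for the visually marked plateau region
in auscultation practice.

Pressure and SPL are correlated after linear interpolation to a common 20 Hz
grid over their overlap and min–max normalization; 20 Hz sits above breath
rates and below the SPL hop rate. Phase slopes are per-breath OLS slopes of
SPL vs time over start→peak and peak→end, averaged across breaths.

Severity is **calibrated, not absolute**: plateau SPL must exceed the
baseline (10th percentile of the SPL series) by a 3 dBA detection margin to
count as a leak at all, then is binned by configurable dBA cut-points
(defaults 58/65 dBA; a value exactly at a cut-point takes the higher class).
The scientifically tested contract is the *monotone ordering* of plateau SPL
and grade in leak strength, because absolute dBA depends on the calibration
offset and recording chain. Volume loss (ml/breath) is accepted from
ventilator data only — never inferred from sound.

## Localization

Cell loudness is the mean SPL over the first 5 s of each recording.
Normalization divides **linear acoustic power** (10^(dBA/10)) by the maximum
cell power, yielding the 0–1 intensity scale with the loudest cell exactly
1.00; dividing in dB would not produce that scale. The leak estimate is the
argmax cell (ties → smallest (row, col), flagged). Grids must be complete;
missing cells are refused rather than interpolated. Coordinates: origin
upper-left, x rightward, y downward, cell centers at index × step; outputs
report 1-based indices. Near-uniform grids (normalized spread < 0.05)
are reported as "no leak detected", matching the uninjured-lung baseline
where normalized intensities cluster in a narrow band.

## Synthetic scenes

The generator's defaults are the study conditions the analysis targets:

- **Ventilation**: rodent preset 70 breaths/min, PIP 16.2 / PEEP 2.1 cmH₂O;
  swine preset 15 breaths/min, PIP 25.2 / PEEP 5 cmH₂O (PEEP 5 plus a
  20.2 cmH₂O driving difference). Waveform: linear rise (30% of the breath),
  plateau hold (20%), exponential decay normalized to reach PEEP exactly at
  breath end.
- **Leak**: sinusoids at k·f₀ with seeded phases; amplitudes chosen so
  plateau band peaks lie on the configured power line (rodent: f₀ 1223 Hz,
  harmonics {1,2,3,4,5,7} — the 6th deliberately missing to exercise gap
  handling — line −0.00231·f − 49.1; swine: f₀ 665 Hz, harmonics {1,2,3,4},
  line −0.00792·f − 34.8). The sum is scaled by
  `strength · ((P(t) − P_amb)/(PIP − P_amb))^exponent`; the
  pressure→loudness exponent is a config knob defaulting to 1, since only a
  correlation, not a law, is empirically established.
- **Ventilator tone**: the rodent preset adds a stationary 890 Hz tone at
  −45 dB — louder than every leak band, as a realistic distractor for the
  series-exclusion logic.
- **Heart**: per beat, two Gaussian-windowed tone bursts (S1 90 Hz,
  S2 120 Hz, 80 ms, S2 at +0.32 s, 60 bpm). The Gaussian envelope makes the
  spectrum Gaussian, so content above 400 Hz is negligible; the generator
  verifies ≥ 99% of power lies below 400 Hz and rejects configs that don't.
- **Ambient**: seeded Gaussian noise at −60 dB RMS re full scale — a floor
  near −94 dB per Welch bin, far below the −80 dB band threshold.
- **Grid**: leak amplitude scales as `standoff / r` with
  `r = √(lateral² + standoff²)` (spherical spreading with a near-field floor
  at the 1 cm microphone standoff — the simplest monotone attenuation law,
  and localization by argmax needs only monotone decay); each cell gets
  independent seeded noise at a configured SNR relative to the leak RMS at
  the source cell.

All randomness flows from a single integer seed (`numpy` `SeedSequence`
spawning per-cell streams); identical configs give bit-identical audio.

What the generator does **not** emulate: broadband turbulent flow noise and
normal breath sounds, bubble-burst transients, time-varying f₀ across the
breath, chest-wall transmission effects, reverberation, and real operating-
room noise. Passing tests therefore demonstrate the correctness of the
analysis chain under the stated model, not clinical performance on recorded
lungs.

## Problem sizes and numerical choices

Band-analysis scenes run 10–20 s at 44.1 kHz; grid simulations use 5 s cells
at 16 kHz (leak content ≤ 2.7 kHz, comfortably under Nyquist), which keeps a
20-replicate 5×5 localization study at a few seconds of compute. Welch
spectra floor at −300 dB internally to avoid log-of-zero; SPL floors at
−120 dB re full scale. High-pass filtering is a 4th-order Butterworth applied
forward–backward (zero phase, −6 dB at the cutoff), preserving leak-burst
timing. WAV I/O accepts mono PCM16/PCM24/float32, normalizing integers by
full scale; writing offers float32 (lossless for this pipeline) and PCM16
with explicit clip control. Resampling is polyphase with a Kaiser (β = 8.6)
window.

## Known limitations

- Absolute dBA values are only as good as the calibration offset; severity
  cut-points are a documented preset to be recalibrated per recording chain.
- Fundamental selection assumes at least three detected bands and can be
  fooled if harmonics are missing *and* a distractor tone fits more ratios
  than the true series.
- The plateau definition (≥ 90% of per-breath peak) degenerates to a sliver
  on triangular (no-hold) pressure waveforms; the assessment then widens to
  the whole breath around the peak.
- Localization assumes one dominant source; two comparable leaks produce a
  bimodal matrix and the argmax reports only the stronger.
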