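"""End-to-end orchestration: assess a recording, localize from a grid
manifest, filter heart sounds, and simulate scenes to disk.

The assessment chain runs SPL -> breath segmentation -> plateau power spectrum
-> band detection -> harmonic series -> band-power regression -> pressure
correlation -> phase slopes -> severity, and collects everything in a
JSON-serializable :class:`AssessmentReport` with input hashes for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import audio_io, bands, breath, dsp, localization, synthetic

__all__ = [
    "AnalysisPreset",
    "PRESETS",
    "AssessmentReport",
    "assess",
    "localize_from_recordings",
    "filter_heart",
    "simulate_to_dir",
    "localize_from_manifest",
]

try:
    _VERSION = version("airleak")
except PackageNotFoundError:  # running from a source tree
    _VERSION = "0+unknown"


@dataclass(frozen=True)
class AnalysisPreset:
    """Analysis parameters for one experimental regime."""

    name: str
    band_threshold_db: float
    band_fmax_hz: float
    band_fmin_hz: float = 400.0  # skip heart-band region
    min_separation_hz: float = 200.0
    ratio_tolerance: float = bands.DEFAULT_RATIO_TOLERANCE
    min_prominence_cmh2o: float = 2.0


#: small-rodent regime: bands above -80 dB in 0-10 kHz;
#: human-sized swine regime: bands above -60 dB in 0-5 kHz
PRESETS = {
    "rat": AnalysisPreset("rat", band_threshold_db=-80.0, band_fmax_hz=10_000.0),
    "swine": AnalysisPreset("swine", band_threshold_db=-60.0, band_fmax_hz=5_000.0),
}


@dataclass
class AssessmentReport:
    preset: str
    spl_summary: dict
    correlation: dict | None
    detected_bands: list[dict]
    harmonic_series: dict | None
    regression: dict | None
    severity: dict
    provenance: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AssessmentReport":
        return cls(**json.loads(text))


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def assess(audio: audio_io.AudioSegment, pressure: audio_io.PressureTrace,
           preset: str | AnalysisPreset = "swine",
           calibration_offset: float = dsp.DEFAULT_CALIBRATION_OFFSET_DB,
           thresholds: breath.SeverityThresholds | None = None,
           provenance: dict | None = None) -> AssessmentReport:
    """Run the full severity-assessment chain on one recording."""
    cfg = PRESETS[preset] if isinstance(preset, str) else preset
    stage = "spl"
    try:
        spl = dsp.spl_series(audio, calibration_offset=calibration_offset)
        stage = "breath segmentation"
        try:
            seg = breath.detect_breaths(pressure, cfg.min_prominence_cmh2o)
        except ValueError:
            seg = None  # no ventilation cycle found; assess the whole recording
        stage = "plateau power spectrum"
        if seg is not None:
            # spectrum from the plateau of the breath with the highest peak
            best = int(np.argmax(seg.peak_pressures))
            t0, t1 = seg.plateau_windows[best]
            if t1 - t0 < 0.05:  # too short to average; widen to the whole breath
                t0, t1 = seg.breaths[best][0], seg.breaths[best][2]
        else:
            t0 = t1 = None
        spectrum = dsp.power_spectrum(audio, t0, t1)
        stage = "band detection"
        band_list = bands.detect_bands(spectrum, cfg.band_threshold_db,
                                       cfg.min_separation_hz,
                                       fmin=cfg.band_fmin_hz,
                                       fmax=cfg.band_fmax_hz)
        stage = "harmonic series"
        series = None
        if len(band_list) >= 3:
            try:
                series = bands.find_harmonic_series(band_list, cfg.ratio_tolerance)
            except ValueError:
                series = None
        stage = "band regression"
        regression = (bands.band_power_regression(band_list)
                      if len(band_list) >= 3 else None)
        stage = "pressure correlation"
        correlation = None
        try:
            correlation = breath.correlate_spl_pressure(spl, pressure)
        except ValueError:
            pass
        stage = "phase slopes"
        slopes = None
        if seg is not None:
            try:
                slopes = breath.phase_slopes(spl, seg)
            except ValueError:
                pass
        stage = "severity"
        if seg is not None:
            plateau_levels = [spl.level[(spl.times >= p0) & (spl.times <= p1)]
                              for p0, p1 in seg.plateau_windows]
            plateau_levels = np.concatenate(
                [x for x in plateau_levels if x.size] or [spl.level])
        else:
            plateau_levels = spl.level
        plateau_spl = float(np.mean(plateau_levels))
        baseline_spl = float(np.percentile(spl.level, 10))
        severity = breath.classify_severity(plateau_spl, baseline_spl,
                                            thresholds, phase_slopes=slopes)
    except ValueError as err:
        raise ValueError(f"assessment failed at stage '{stage}': {err}") from err

    return AssessmentReport(
        preset=cfg.name,
        spl_summary={"min_dba": float(spl.level.min()),
                     "max_dba": float(spl.level.max()),
                     "mean_dba": float(spl.level.mean()),
                     "window_s": spl.window_s, "hop_s": spl.hop_s,
                     "calibration_offset_db": spl.calibration_offset},
        correlation=(None if correlation is None else
                     {"rho": correlation.rho, "n_pairs": correlation.n_pairs,
                      "common_rate_hz": correlation.common_rate_hz}),
        detected_bands=[{"label": b.label, "center_hz": b.center_hz,
                         "peak_power_db": b.peak_power_db,
                         "bandwidth_hz": b.bandwidth_hz} for b in band_list],
        harmonic_series=(None if series is None else
                         {"fundamental_hz": series.fundamental_hz,
                          "harmonic_numbers": series.harmonic_numbers,
                          "members": [b.label for b, _ in series.members],
                          "excluded": [b.label for b in series.excluded]}),
        regression=(None if regression is None else
                    {"slope_db_per_hz": regression.slope,
                     "intercept_db": regression.intercept,
                     "r_squared": regression.r_squared,
                     "p_value": regression.p_value, "n": regression.n}),
        severity={"class": severity.severity_class,
                  "plateau_spl_dba": severity.plateau_spl_dba,
                  "baseline_spl_dba": severity.baseline_spl_dba,
                  "phase_slopes_dba_per_s": slopes},
        provenance={"version": _VERSION, **(provenance or {})},
    )


#: normalized-intensity spread below which an ambient-only grid is declared
NO_LEAK_SPREAD = 0.05


def localize_from_recordings(recordings, n_rows: int, n_cols: int,
                             step_cm: float = 1.0, duration_s: float = 5.0):
    """Build, normalize and argmax the intensity matrix; flag no-leak grids.

    Returns ``(matrix, location_or_None)``: when the normalized spread
    (max - min) is below :data:`NO_LEAK_SPREAD` the grid is near-uniform and
    no leak is declared.
    """
    matrix = localization.build_matrix(recordings, n_rows, n_cols, step_cm,
                                       duration_s)
    matrix = localization.normalize_matrix(matrix)
    spread = float(np.ptp(matrix.normalized))
    if spread < NO_LEAK_SPREAD:
        return matrix, None
    return matrix, localization.locate_leak(matrix)


def localize_from_manifest(manifest_csv, step_cm: float = 1.0,
                           duration_s: float = 5.0):
    """Localize from a grid manifest CSV with columns row, col, wav_path."""
    frame = pd.read_csv(manifest_csv)
    missing = {"row", "col", "wav_path"} - set(frame.columns)
    if missing:
        raise ValueError(f"{manifest_csv}: missing column(s) {sorted(missing)}")
    base = Path(manifest_csv).parent
    recordings = []
    for _, rec in frame.iterrows():
        path = Path(rec["wav_path"])
        if not path.is_absolute():
            path = base / path
        recordings.append(((int(rec["row"]), int(rec["col"])),
                           audio_io.read_wav(path)))
    n_rows = int(frame["row"].max()) + 1
    n_cols = int(frame["col"].max()) + 1
    return localize_from_recordings(recordings, n_rows, n_cols, step_cm,
                                    duration_s)


def filter_heart(segment: audio_io.AudioSegment, cutoff_hz: float = 500.0,
                 order: int = 4):
    """High-pass filter a mixture to remove heart sounds.

    Returns ``(filtered_segment, removed_low_band_db)`` where the second
    element is the drop in sub-cutoff power in dB.
    """
    filtered = dsp.highpass(segment, cutoff_hz, order)

    def low_power(seg):
        spec = np.abs(np.fft.rfft(seg.samples)) ** 2
        freqs = np.fft.rfftfreq(seg.samples.size, 1 / seg.sample_rate)
        return float(spec[freqs < cutoff_hz].sum())

    before, after = low_power(segment), low_power(filtered)
    removed_db = 10.0 * np.log10(max(before, 1e-30) / max(after, 1e-30))
    return filtered, removed_db


def simulate_to_dir(config: synthetic.SceneConfig, out_dir,
                    grid: tuple[int, int] | None = None,
                    leak_cell: tuple[int, int] | None = None,
                    step_cm: float = 1.0, snr_db: float = 10.0) -> dict:
    """Write a simulated scene (or grid of recordings) to a directory.

    Single scene: scene.wav + pressure.csv + truth.json. Grid: one WAV per
    cell plus manifest.csv compatible with :func:`localize_from_manifest`.
    Returns a dict of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    if grid is None:
        audio, truth = synthetic.gen_scene(config)
        audio_io.write_wav(audio, out / "scene.wav")
        audio_io.write_pressure_csv(truth.pressure, out / "pressure.csv")
        written = {"wav": str(out / "scene.wav"),
                   "pressure": str(out / "pressure.csv")}
    else:
        n_rows, n_cols = grid
        recordings, truth = synthetic.gen_grid_recordings(
            config, n_rows, n_cols, step_cm=step_cm, leak_cell=leak_cell,
            snr_db=snr_db)
        rows = []
        for (r, c), seg in recordings:
            name = f"cell_{r}_{c}.wav"
            audio_io.write_wav(seg, out / name)
            rows.append({"row": r, "col": c, "wav_path": name})
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
        audio_io.write_pressure_csv(truth.pressure, out / "pressure.csv")
        written = {"manifest": str(out / "manifest.csv"),
                   "pressure": str(out / "pressure.csv")}
    truth_json = {
        "seed": truth.seed,
        "fundamental_hz": truth.fundamental_hz,
        "harmonic_numbers": list(truth.harmonic_numbers),
        "component_gains": truth.component_gains,
        "leak_cell": truth.leak_cell,
        "leak_position_cm": truth.leak_position_cm,
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=2))
    written["truth"] = str(out / "truth.json")
    return written
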