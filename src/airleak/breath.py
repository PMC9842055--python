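"""Breath segmentation, pressure-loudness correlation, phase slopes, and
severity grading.

Positive-pressure ventilation drives the leak: airflow through the pleural
defect scales with airway pressure, so leak loudness rises during inspiration,
peaks at the inspiratory plateau, and falls during expiration. The plateau
window (samples within 90% of each breath's peak pressure) is where leak
spectra are extracted, and the plateau SPL is the severity readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .audio_io import PressureTrace
from .dsp import SPLSeries

__all__ = [
    "BreathSegmentation",
    "CorrelationResult",
    "SeverityReport",
    "SeverityThresholds",
    "detect_breaths",
    "peak_pressure_decline",
    "correlate_spl_pressure",
    "phase_slopes",
    "classify_severity",
]

#: fraction of per-breath peak pressure defining the inspiratory plateau
PLATEAU_FRACTION_OF_PEAK = 0.90
#: plateau SPL must exceed baseline by this margin (dBA) to call a leak at all
DEFAULT_DETECTION_MARGIN_DB = 3.0


@dataclass
class BreathSegmentation:
    """Breaths as (t_start, t_peak, t_end) with peak pressures and plateaus."""

    breaths: list[tuple[float, float, float]]
    peak_pressures: np.ndarray
    plateau_windows: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for (s, p, e), (p0, p1) in zip(self.breaths, self.plateau_windows):
            if not (s <= p <= e):
                raise ValueError("breath peak outside its boundaries")
            if not (s <= p0 <= p1 <= e):
                raise ValueError("plateau window outside its breath")

    @property
    def n_breaths(self) -> int:
        return len(self.breaths)


@dataclass
class CorrelationResult:
    """Pearson correlation between SPL and airway pressure on a common grid."""

    rho: float
    n_pairs: int
    common_rate_hz: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"invalid correlation {self.rho}")
        if self.n_pairs < 3:
            raise ValueError("correlation needs >= 3 paired samples")


@dataclass
class SeverityThresholds:
    """dBA cut-points of the severity grades (calibrated preset, not absolute).

    ``mild_max`` and ``moderate_max`` split leak-positive recordings into
    mild (< mild_max), moderate ([mild_max, moderate_max)) and severe
    (>= moderate_max); a plateau exactly at a cut-point goes to the higher
    class. ``detection_margin_db`` above baseline is required to call a leak.
    """

    mild_max: float = 58.0
    moderate_max: float = 65.0
    detection_margin_db: float = DEFAULT_DETECTION_MARGIN_DB

    def __post_init__(self) -> None:
        if not self.mild_max < self.moderate_max:
            raise ValueError("severity cut-points must be strictly increasing")


@dataclass
class SeverityReport:
    plateau_spl_dba: float
    baseline_spl_dba: float
    severity_class: str
    volume_loss_ml_per_breath: float | None = None
    phase_slopes: tuple[float, float] | None = None


def detect_breaths(trace: PressureTrace,
                   min_prominence: float = 2.0) -> BreathSegmentation:
    """Segment a pressure trace into breaths.

    Inspiratory peaks are found by prominence; each breath runs from the
    pressure minimum before its peak to the minimum after it. The plateau is
    the contiguous run of samples at or above 90% of that breath's peak.
    """
    peaks, _ = signal.find_peaks(trace.pressure, prominence=min_prominence)
    if peaks.size == 0:
        raise ValueError(
            f"no pressure peak with prominence >= {min_prominence} cmH2O")
    t, p = trace.times, trace.pressure
    breaths: list[tuple[float, float, float]] = []
    plateaus: list[tuple[float, float]] = []
    peak_pressures = []
    for i, pk in enumerate(peaks):
        left = peaks[i - 1] if i > 0 else 0
        right = peaks[i + 1] if i < peaks.size - 1 else p.size - 1
        i_start = left + int(np.argmin(p[left:pk + 1]))
        i_end = pk + int(np.argmin(p[pk:right + 1]))
        limit = PLATEAU_FRACTION_OF_PEAK * p[pk]
        lo = pk
        while lo > i_start and p[lo - 1] >= limit:
            lo -= 1
        hi = pk
        while hi < i_end and p[hi + 1] >= limit:
            hi += 1
        breaths.append((float(t[i_start]), float(t[pk]), float(t[i_end])))
        plateaus.append((float(t[lo]), float(t[hi])))
        peak_pressures.append(float(p[pk]))
    return BreathSegmentation(breaths, np.asarray(peak_pressures), plateaus)


def peak_pressure_decline(baseline_peak: float, injured_peak: float,
                          ndigits: int = 0) -> float:
    """Percent decline in peak inspiratory pressure after injury.

    ``100 * (baseline - injured) / baseline``, rounded to ``ndigits``.
    """
    if not baseline_peak > 0:
        raise ValueError("baseline peak pressure must be positive")
    return round(100.0 * (baseline_peak - injured_peak) / baseline_peak, ndigits)


def correlate_spl_pressure(spl: SPLSeries, trace: PressureTrace,
                           common_rate_hz: float = 20.0) -> CorrelationResult:
    """Pearson correlation between loudness and airway pressure.

    Both series are linearly interpolated onto a common grid over their
    overlapping time support, min-max normalized to 0..1, and correlated.
    The result is symmetric and invariant to affine rescaling of either input.
    """
    t0 = max(spl.times[0], trace.times[0])
    t1 = min(spl.times[-1], trace.times[-1])
    n = int(np.floor((t1 - t0) * common_rate_hz)) + 1
    if t1 <= t0 or n < 3:
        raise ValueError("insufficient overlapping time support")
    grid = t0 + np.arange(n) / common_rate_hz
    a = np.interp(grid, spl.times, spl.level)
    b = np.interp(grid, trace.times, trace.pressure)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("undefined correlation: a series has zero variance")
    a = (a - a.min()) / np.ptp(a)
    b = (b - b.min()) / np.ptp(b)
    rho = float(stats.pearsonr(a, b).statistic)
    return CorrelationResult(rho=rho, n_pairs=n, common_rate_hz=common_rate_hz)


def phase_slopes(spl: SPLSeries,
                 seg: BreathSegmentation) -> tuple[float, float]:
    """Mean loudness slope (dBA/s) during inspiration and expiration.

    Per breath, OLS slope of SPL versus time over start->peak (inspiration)
    and peak->end (expiration), averaged across breaths. Breaths whose phase
    covers fewer than two SPL samples are skipped with a warning.
    """
    insp, exp = [], []
    for t_start, t_peak, t_end in seg.breaths:
        for (lo, hi), bucket in (((t_start, t_peak), insp),
                                 ((t_peak, t_end), exp)):
            mask = (spl.times >= lo) & (spl.times <= hi)
            if mask.sum() < 2:
                warnings.warn(
                    f"phase [{lo:.3f}, {hi:.3f}] s has <2 SPL samples; skipped",
                    stacklevel=2)
                continue
            tt, yy = spl.times[mask], spl.level[mask]
            if np.ptp(yy) == 0:
                bucket.append(0.0)
            else:
                bucket.append(float(stats.linregress(tt, yy).slope))
    if not insp or not exp:
        raise ValueError("no breath provided enough SPL samples for a slope")
    return float(np.mean(insp)), float(np.mean(exp))


def classify_severity(plateau_spl_dba: float, baseline_spl_dba: float,
                      thresholds: SeverityThresholds | None = None,
                      volume_loss_ml_per_breath: float | None = None,
                      phase_slopes: tuple[float, float] | None = None,
                      ) -> SeverityReport:
    """Grade leak severity from plateau loudness.

    ``none`` when the plateau SPL does not exceed baseline by the detection
    margin; otherwise binned by the configured dBA cut-points, with a plateau
    exactly at a cut-point assigned to the higher class. Volume loss, when
    supplied, comes from ventilator data — it is never inferred from sound.
    """
    thr = thresholds or SeverityThresholds()
    if plateau_spl_dba <= baseline_spl_dba + thr.detection_margin_db:
        cls = "none"
    elif plateau_spl_dba < thr.mild_max:
        cls = "mild"
    elif plateau_spl_dba < thr.moderate_max:
        cls = "moderate"
    else:
        cls = "severe"
    return SeverityReport(plateau_spl_dba=plateau_spl_dba,
                          baseline_spl_dba=baseline_spl_dba,
                          severity_class=cls,
                          volume_loss_ml_per_breath=volume_loss_ml_per_breath,
                          phase_slopes=phase_slopes)
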