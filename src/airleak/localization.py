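"""Leak localization from a grid of per-position loudness measurements.

A microphone is stepped across the lung surface on a regular grid (1 cm step
in the reference protocol, upper-left origin, row-major traversal), recording
a few seconds per cell. Mean A-weighted loudness per cell forms the sound
intensity matrix; after normalizing linear acoustic power by its maximum the
leak site is the cell reading 1.00.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioSegment
from .dsp import DEFAULT_CALIBRATION_OFFSET_DB, spl_series

__all__ = [
    "IntensityMatrix",
    "LeakLocation",
    "point_loudness",
    "build_matrix",
    "normalize_matrix",
    "locate_leak",
    "localization_error",
]


@dataclass
class IntensityMatrix:
    """Grid of per-cell mean loudness (dBA) and its 0..1 normalization."""

    raw_dba: np.ndarray
    step_cm: float = 1.0
    normalized: np.ndarray | None = None
    origin: str = "upper-left"
    traversal: str = "row-major"

    def __post_init__(self) -> None:
        self.raw_dba = np.asarray(self.raw_dba, dtype=np.float64)
        if self.raw_dba.ndim != 2:
            raise ValueError("intensity matrix must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.raw_dba.shape[0]

    @property
    def n_cols(self) -> int:
        return self.raw_dba.shape[1]


@dataclass
class LeakLocation:
    """Located leak cell, its center position, and the peak intensity there."""

    cell: tuple[int, int]
    position_cm: tuple[float, float]
    peak_normalized_intensity: float
    tie: bool = False


def point_loudness(segment: AudioSegment, duration_s: float = 5.0,
                   calibration_offset: float = DEFAULT_CALIBRATION_OFFSET_DB,
                   ) -> float:
    """Mean A-weighted SPL (dBA) over the first ``duration_s`` of a recording."""
    if segment.duration + 1e-9 < duration_s:
        raise ValueError(
            f"segment ({segment.duration:.2f} s) shorter than {duration_s} s")
    window = segment.crop(segment.start_time, segment.start_time + duration_s)
    series = spl_series(window, calibration_offset=calibration_offset)
    return float(np.mean(series.level))


def build_matrix(recordings: list[tuple[tuple[int, int], AudioSegment]],
                 n_rows: int, n_cols: int, step_cm: float = 1.0,
                 duration_s: float = 5.0,
                 calibration_offset: float = DEFAULT_CALIBRATION_OFFSET_DB,
                 ) -> IntensityMatrix:
    """Assemble the sound intensity matrix from per-cell recordings.

    Every grid cell must be present exactly once (input order is irrelevant);
    missing or duplicate cells are an error naming the offenders — absent
    cells are never interpolated, since that could fabricate a hotspot.
    """
    seen: dict[tuple[int, int], AudioSegment] = {}
    duplicates = []
    for cell, segment in recordings:
        if cell in seen:
            duplicates.append(cell)
        seen[tuple(cell)] = segment
    expected = {(r, c) for r in range(n_rows) for c in range(n_cols)}
    missing = sorted(expected - set(seen))
    extra = sorted(set(seen) - expected)
    if missing or duplicates or extra:
        raise ValueError(
            f"grid incomplete: missing={missing} duplicate={sorted(duplicates)} "
            f"outside={extra}")
    raw = np.empty((n_rows, n_cols))
    for (r, c), segment in seen.items():
        raw[r, c] = point_loudness(segment, duration_s, calibration_offset)
    return IntensityMatrix(raw_dba=raw, step_cm=step_cm)


def normalize_matrix(matrix: IntensityMatrix) -> IntensityMatrix:
    """Normalize linear acoustic power per cell by the maximum cell power.

    Division happens in the linear power domain (10^(dBA/10)), not in dB, so
    the result spans 0..1 with the loudest cell exactly 1.0.
    """
    power = 10.0 ** (matrix.raw_dba / 10.0)
    peak = float(np.max(power))
    if peak <= 0 or not np.isfinite(peak):
        raise ValueError("no signal: all-zero acoustic power")
    return IntensityMatrix(raw_dba=matrix.raw_dba, step_cm=matrix.step_cm,
                           normalized=power / peak, origin=matrix.origin,
                           traversal=matrix.traversal)


def locate_leak(matrix: IntensityMatrix) -> LeakLocation:
    """Leak cell = argmax of normalized intensity.

    Ties are broken toward the smallest (row, col) and flagged. Cell centers
    are at (col*step, row*step) cm with x rightward and y downward from the
    upper-left origin.
    """
    if matrix.normalized is None:
        raise ValueError("normalize_matrix must be applied first")
    norm = matrix.normalized
    peak = float(np.max(norm))
    rows, cols = np.nonzero(norm == peak)
    order = np.lexsort((cols, rows))
    r, c = int(rows[order[0]]), int(cols[order[0]])
    return LeakLocation(cell=(r, c),
                        position_cm=(c * matrix.step_cm, r * matrix.step_cm),
                        peak_normalized_intensity=peak,
                        tie=rows.size > 1)


def localization_error(estimate: LeakLocation,
                       truth_position_cm: tuple[float, float]) -> float:
    """Euclidean distance (cm) between the located cell center and the truth."""
    dx = estimate.position_cm[0] - truth_position_cm[0]
    dy = estimate.position_cm[1] - truth_position_cm[1]
    return float(np.hypot(dx, dy))
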