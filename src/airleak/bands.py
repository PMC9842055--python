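"""Spectral band detection, harmonic-series identification, and band-power
regression.

Air leaks excite the pleural tissue at its resonance and overtones, so the
plateau power spectrum shows a small set of narrow bands at near-integer
multiples of a fundamental. Ventilator tones and ambient peaks appear as
additional bands that do not fit the integer-ratio structure; they are kept
but flagged as excluded from the harmonic series. Band power falls roughly
linearly with frequency, which an ordinary least-squares fit quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .dsp import PowerSpectrum

__all__ = [
    "FrequencyBand",
    "HarmonicSeries",
    "BandRegression",
    "detect_bands",
    "harmonic_number",
    "find_harmonic_series",
    "band_power_regression",
    "DEFAULT_RATIO_TOLERANCE",
]

#: default tolerance on the harmonic ratio residual |f/f0 - k|
DEFAULT_RATIO_TOLERANCE = 0.25


@dataclass
class FrequencyBand:
    """A detected narrow spectral band."""

    center_hz: float
    peak_power_db: float
    label: str = ""
    bandwidth_hz: float = 0.0

    def __post_init__(self) -> None:
        if not self.center_hz > 0:
            raise ValueError("band center must be positive")


@dataclass
class HarmonicSeries:
    """A fundamental with bands assigned integer harmonic numbers.

    ``members`` pairs each explained band with its harmonic number (strictly
    increasing, gaps allowed); bands that fit no integer ratio within
    ``tolerance`` are listed in ``excluded``.
    """

    fundamental_hz: float
    members: list[tuple[FrequencyBand, int]]
    tolerance: float
    excluded: list[FrequencyBand] = field(default_factory=list)

    @property
    def harmonic_numbers(self) -> list[int]:
        return [k for _, k in self.members]


@dataclass
class BandRegression:
    """OLS fit of band peak power (dB) on band center frequency (Hz)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def detect_bands(spectrum: PowerSpectrum, threshold_db: float = -80.0,
                 min_separation_hz: float = 200.0, fmin: float = 0.0,
                 fmax: float = 10_000.0) -> list[FrequencyBand]:
    """Find narrow spectral bands above a power threshold.

    Local maxima of the spectrum in [fmin, fmax] above ``threshold_db`` are
    located; maxima closer than ``min_separation_hz`` are merged keeping the
    stronger. Each band's center is the power-weighted centroid of the
    contiguous bins within 3 dB of its peak, and its bandwidth is that
    region's width. Bands are returned ascending and labeled fb1..fbN.
    An empty list is a valid result.
    """
    if not fmin < fmax:
        raise ValueError("require fmin < fmax")
    if spectrum.frequencies.size == 0:
        raise ValueError("empty spectrum")
    sel = (spectrum.frequencies >= fmin) & (spectrum.frequencies <= fmax)
    freqs = spectrum.frequencies[sel]
    power = spectrum.power[sel]
    if freqs.size < 3:
        raise ValueError("spectrum has too few bins in the analysis range")
    df = float(np.median(np.diff(freqs)))
    distance = max(1, int(round(min_separation_hz / df)))
    peaks, _ = signal.find_peaks(power, height=threshold_db, distance=distance)

    out: list[FrequencyBand] = []
    for p in peaks:
        limit = power[p] - 3.0
        lo = p
        while lo > 0 and power[lo - 1] >= limit:
            lo -= 1
        hi = p
        while hi < power.size - 1 and power[hi + 1] >= limit:
            hi += 1
        weights = 10.0 ** (power[lo:hi + 1] / 10.0)
        center = float(np.sum(freqs[lo:hi + 1] * weights) / np.sum(weights))
        out.append(FrequencyBand(center_hz=center,
                                 peak_power_db=float(power[p]),
                                 bandwidth_hz=float(freqs[hi] - freqs[lo])))
    out.sort(key=lambda b: b.center_hz)
    for i, band in enumerate(out):
        band.label = f"fb{i + 1}"
    return out


def harmonic_number(frequency: float, fundamental: float,
                    tolerance: float = DEFAULT_RATIO_TOLERANCE) -> int | None:
    """Nearest-integer harmonic number of ``frequency`` re ``fundamental``.

    Returns ``k = round(frequency / fundamental)`` when the ratio residual
    ``|frequency/fundamental - k|`` is within ``tolerance`` and k >= 1,
    otherwise ``None``.
    """
    if not fundamental > 0:
        raise ValueError("fundamental must be positive")
    ratio = frequency / fundamental
    k = int(round(ratio))
    if k >= 1 and abs(ratio - k) <= tolerance:
        return k
    return None


def find_harmonic_series(bands: list[FrequencyBand],
                         tolerance: float = DEFAULT_RATIO_TOLERANCE,
                         min_members: int = 3) -> HarmonicSeries:
    """Identify the harmonic series among detected bands.

    Every band is tried as the fundamental; the one whose integer-ratio fit
    explains the most bands wins (ties broken toward the lowest frequency).
    The loudest band need not be the fundamental — a ventilator tone can
    dominate the spectrum yet fit no integer ratio, in which case it lands in
    ``excluded``. Harmonic numbers may skip integers (a series can lack, e.g.,
    the 6th harmonic). If two bands map to the same harmonic number, the one
    with the smaller ratio residual is kept.
    """
    if len(bands) < min_members:
        raise ValueError(
            f"need at least {min_members} bands, got {len(bands)}")

    def assignment(f0: float) -> dict[int, FrequencyBand]:
        assigned: dict[int, tuple[FrequencyBand, float]] = {}
        for band in bands:
            k = harmonic_number(band.center_hz, f0, tolerance)
            if k is None:
                continue
            residual = abs(band.center_hz / f0 - k)
            if k not in assigned or residual < assigned[k][1]:
                assigned[k] = (band, residual)
        return {k: b for k, (b, _) in assigned.items()}

    best: tuple[int, float, dict[int, FrequencyBand]] | None = None
    for candidate in sorted(bands, key=lambda b: b.center_hz):
        members = assignment(candidate.center_hz)
        score = len(members)
        if best is None or score > best[0]:
            best = (score, candidate.center_hz, members)

    assert best is not None
    score, fundamental, members = best
    if score < min_members:
        raise ValueError(
            f"no fundamental explains >= {min_members} bands; best candidate "
            f"{fundamental:.1f} Hz explains {score}")
    member_list = sorted(((band, k) for k, band in members.items()),
                         key=lambda item: item[1])
    member_bands = {id(band) for band, _ in member_list}
    excluded = [band for band in bands if id(band) not in member_bands]
    return HarmonicSeries(fundamental_hz=fundamental, members=member_list,
                          tolerance=tolerance, excluded=excluded)


def band_power_regression(bands: list[FrequencyBand]) -> BandRegression:
    """OLS of band peak power (dB) on center frequency (Hz).

    Reports the two-sided p-value for a zero slope. A set of bands with
    constant power is handled explicitly (slope 0, R^2 0) instead of the
    nan that a naive correlation would produce.
    """
    if len(bands) < 3:
        raise ValueError(f"regression needs >= 3 bands, got {len(bands)}")
    x = np.array([b.center_hz for b in bands], dtype=np.float64)
    y = np.array([b.peak_power_db for b in bands], dtype=np.float64)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all bands at the same frequency")
    if np.ptp(y) == 0:
        return BandRegression(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                              p_value=1.0, n=len(bands))
    fit = stats.linregress(x, y)
    return BandRegression(slope=float(fit.slope), intercept=float(fit.intercept),
                          r_squared=float(fit.rvalue ** 2),
                          p_value=float(fit.pvalue), n=len(bands))
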