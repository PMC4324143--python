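"""Spectral analysis: baselines, peaks, metachromatic shift, bleaching fits.

Operations cover 1D absorption/emission spectra, 2D excitation–emission
scans, and photobleaching time series.  Peak positions are reported on the
sampling grid by default (matching how band maxima are read off recorded
spectra); parabolic sub-grid refinement is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "Spectrum",
    "Lambda2Scan",
    "BleachSeries",
    "BleachFit",
    "subtract_baseline",
    "find_peak",
    "peak_shift",
    "lambda2_max",
    "normalize_scan",
    "fit_bleach",
]


@dataclass
class Spectrum:
    """Intensity versus wavelength.

    ``wavelengths`` (nm) must be strictly increasing and the same length as
    ``intensities``; at least 3 points are required for peak finding.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    kind: Literal["absorption", "emission"] = "absorption"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1D")
        if self.wavelengths.size != self.intensities.size:
            raise ValueError("wavelengths and intensities must have equal length")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass
class Lambda2Scan:
    """Excitation × emission intensity matrix.

    ``intensities[i, j]`` is the signal at excitation ``excitation_nm[i]``
    and emission band centre ``emission_nm[j]``.
    """

    excitation_nm: np.ndarray
    emission_nm: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.excitation_nm = np.asarray(self.excitation_nm, dtype=float)
        self.emission_nm = np.asarray(self.emission_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.excitation_nm.size, self.emission_nm.size):
            raise ValueError(
                "intensity matrix shape "
                f"{self.intensities.shape} does not match grids "
                f"({self.excitation_nm.size}, {self.emission_nm.size})"
            )


@dataclass
class BleachSeries:
    """Per-frame signal intensity during repeated scanning."""

    frame: np.ndarray
    time_s: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (self.frame.size == self.time_s.size == self.intensity.size):
            raise ValueError("frame, time_s and intensity must have equal length")
        if np.any(np.diff(self.time_s) < 0):
            raise ValueError("time must be non-decreasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    def __len__(self) -> int:
        return int(self.frame.size)


def subtract_baseline(stained: Spectrum, unstained: Spectrum) -> Spectrum:
    """Pointwise ``stained − unstained`` on an identical wavelength grid.

    The grids must match exactly — no silent interpolation.  Negative
    differences are retained and flagged in ``meta['has_negative']``.
    """
    if stained.wavelengths.size != unstained.wavelengths.size or not np.array_equal(
        stained.wavelengths, unstained.wavelengths
    ):
        raise ValueError("wavelength grids differ; resample explicitly before subtracting")
    diff = stained.intensities - unstained.intensities
    meta = dict(stained.meta)
    meta["baseline_subtracted"] = True
    meta["has_negative"] = bool(np.any(diff < 0))
    return Spectrum(stained.wavelengths.copy(), diff, kind=stained.kind, meta=meta)


def find_peak(spectrum: Spectrum, refine: bool = False) -> float:
    """Wavelength (nm) of the global intensity maximum.

    Ties are broken toward the shorter wavelength.  With ``refine=True`` a
    3-point parabola through the maximum and its neighbours interpolates a
    sub-grid position; the default reports the grid point itself.
    """
    if len(spectrum) < 3:
        raise ValueError("peak finding needs at least 3 points")
    y = spectrum.intensities
    if np.ptp(y) == 0:
        raise ValueError("flat spectrum has no peak")
    i = int(np.argmax(y))  # argmax returns the first max: shortest wavelength
    if not refine or i == 0 or i == y.size - 1:
        return float(spectrum.wavelengths[i])
    x0, x1, x2 = spectrum.wavelengths[i - 1 : i + 2]
    y0, y1, y2 = y[i - 1 : i + 2]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x1)
    # vertex of the parabola through the three points (uniform-grid form)
    offset = 0.5 * (y0 - y2) / denom
    return float(x1 + offset * (x2 - x0) / 2.0)


def peak_shift(reference: Spectrum, bound: Spectrum, refine: bool = False) -> float:
    """Signed peak shift ``find_peak(reference) − find_peak(bound)`` in nm.

    Positive values are hypsochromic (blue) shifts of the bound form
    relative to the reference.
    """
    return find_peak(reference, refine=refine) - find_peak(bound, refine=refine)


def lambda2_max(scan: Lambda2Scan) -> dict:
    """Locate the global maximum of an excitation–emission matrix.

    Returns a dict with the grid coordinates of the maximum and the
    excitation band (min, max nm) over which the per-excitation maximum
    stays at or above 90% of the global maximum — a compact description of
    broad excitation ranges.
    """
    m = scan.intensities
    if m.size == 0:
        raise ValueError("empty scan")
    if np.ptp(m) == 0:
        if m.size == 1:
            return {
                "excitation_nm": float(scan.excitation_nm[0]),
                "emission_nm": float(scan.emission_nm[0]),
                "excitation_band_90": (
                    float(scan.excitation_nm[0]),
                    float(scan.excitation_nm[0]),
                ),
            }
        raise ValueError("flat scan has no maximum")
    i, j = np.unravel_index(int(np.argmax(m)), m.shape)
    row_max = m.max(axis=1)
    band = scan.excitation_nm[row_max >= 0.9 * m[i, j]]
    return {
        "excitation_nm": float(scan.excitation_nm[i]),
        "emission_nm": float(scan.emission_nm[j]),
        "excitation_band_90": (float(band.min()), float(band.max())),
    }


def normalize_scan(data: Spectrum | Lambda2Scan) -> Spectrum | Lambda2Scan:
    """Min–max scale intensities to [0, 1]; errors on constant input."""
    x = data.intensities
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("cannot normalize a constant signal")
    scaled = (x - lo) / (hi - lo)
    meta = dict(data.meta)
    meta["normalized"] = True
    if isinstance(data, Spectrum):
        return Spectrum(data.wavelengths.copy(), scaled, kind=data.kind, meta=meta)
    return Lambda2Scan(data.excitation_nm.copy(), data.emission_nm.copy(), scaled, meta=meta)


@dataclass
class BleachFit:
    """OLS line through a normalized bleaching series.

    ``slope`` and ``intercept`` are in fraction-of-initial-signal per unit
    of the chosen abscissa (frame index or seconds).
    """

    slope: float
    intercept: float
    by: Literal["frame", "time"]
    r_value: float

    def fraction_remaining(self, t: float) -> float:
        return self.intercept + self.slope * t

    def percent_remaining(self, t: float) -> float:
        return 100.0 * self.fraction_remaining(t)

    def percent_decrease(self, t: float) -> float:
        return 100.0 - self.percent_remaining(t)


def fit_bleach(series: BleachSeries, by: Literal["frame", "time"] = "frame") -> BleachFit:
    """Linear regression of signal (normalized to frame zero) vs frame/time.

    The series is divided by its first value before fitting, so the
    intercept of a noise-free series is 1.
    """
    if len(series) < 2:
        raise ValueError("bleach fitting needs at least 2 frames")
    if series.intensity[0] == 0:
        raise ValueError("cannot normalize: signal at time zero is 0")
    y = series.intensity / series.intensity[0]
    x = series.frame.astype(float) if by == "frame" else series.time_s
    if np.ptp(x) == 0:
        raise ValueError("abscissa is constant; cannot fit a line")
    res = stats.linregress(x, y)
    if np.ptp(y) == 0:
        # linregress r is nan for constant y; a flat series is a perfect fit
        return BleachFit(slope=0.0, intercept=float(y[0]), by=by, r_value=1.0)
    return BleachFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        by=by,
        r_value=float(res.rvalue),
    )


def exponential_bleach_diagnostic(series: BleachSeries, by: str = "frame") -> dict:
    """Log-linear exponential fit, offered as a diagnostic alongside the
    linear model (the linear fit is the reported quantity)."""
    y = series.intensity / series.intensity[0]
    if np.any(y <= 0):
        warnings.warn("non-positive values dropped for exponential diagnostic")
    keep = y > 0
    x = (series.frame.astype(float) if by == "frame" else series.time_s)[keep]
    res = stats.linregress(x, np.log(y[keep]))
    return {"rate_per_unit": -float(res.slope), "log_intercept": float(res.intercept)}
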