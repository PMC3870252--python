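"""Stoichiometry periodicity detection via a power spectrum.

Spot intensities are converted to molecule counts by dividing by the
single-fluorophore unit intensity; the distribution of those counts is then
searched for periodic structure.  A population built from a q-mer oligomeric
unit produces values clustered at multiples of q, and the squared modulus of
the Fourier transform of the (kernel-smoothed, mean-subtracted) distribution
shows a peak at periodicity q molecules.

Construction: Gaussian KDE on a uniform grid (reflected at zero and
renormalised, since stoichiometries are nonnegative), mean subtraction to
remove the DC term only, zero-padding to 4× the grid for smooth peak
interpolation, and reindexing from frequency f (cycles per molecule) to
periodicity 1/f (molecules).  The dominant peak is the largest local maximum
of power within the search range, refined by quadratic interpolation, with a
half-width at half maximum measured on the periodicity axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quantify import UnitIntensity

__all__ = [
    "StoichiometrySet",
    "PeriodicityResult",
    "to_stoichiometry",
    "stoichiometry_se",
    "stoichiometry_density",
    "periodicity_spectrum",
    "find_peak",
    "analyze_periodicity",
]

DEFAULT_BANDWIDTH = 0.7  # molecules; comparable to single-fluorophore spread
DEFAULT_SEARCH_RANGE = (2.0, 20.0)  # molecules


@dataclass
class StoichiometrySet:
    """Real-valued molecule counts for a set of spots, with optional per-spot
    metadata (cell length, constriction class)."""

    values: np.ndarray
    cell_length_um: np.ndarray | None = None
    constriction_class: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("stoichiometries must be nonnegative")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PeriodicityResult:
    """Power spectrum over the periodicity axis plus the dominant peak."""

    periodicity_grid: np.ndarray  # molecules, ascending
    power: np.ndarray
    search_range: tuple[float, float]
    peak_periodicity: float | None = None
    peak_hwhm: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def has_peak(self) -> bool:
        return self.peak_periodicity is not None


def to_stoichiometry(intensity, unit: UnitIntensity) -> np.ndarray | float:
    """Convert integrated intensity (counts) to molecules: intensity / unit."""
    if unit.mean <= 0:
        raise ValueError("unit intensity must be positive")
    return np.asarray(intensity, dtype=float) / unit.mean


def stoichiometry_se(intensity, unit: UnitIntensity) -> np.ndarray | float:
    """Propagated standard error of the stoichiometry from the unit-intensity
    calibration uncertainty (measurement noise of the spot not included)."""
    s = np.asarray(intensity, dtype=float) / unit.mean
    return np.abs(s) * unit.se / unit.mean


def stoichiometry_density(
    values, bandwidth: float = DEFAULT_BANDWIDTH
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of stoichiometry values on a uniform grid.

    The grid runs from 0 to max(values) + 4 bandwidths with step bandwidth/4.
    Kernel mass falling below zero is reflected back (counts are nonnegative)
    and the density is renormalised to integrate to exactly 1 on the grid.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError(f"need at least 5 values, got {values.size}")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    step = bandwidth / 4.0
    hi = float(values.max()) + 4.0 * bandwidth
    grid = np.arange(0.0, hi + step / 2, step)
    diff = (grid[None, :] - values[:, None]) / bandwidth
    refl = (grid[None, :] + values[:, None]) / bandwidth
    density = (np.exp(-0.5 * diff**2) + np.exp(-0.5 * refl**2)).sum(axis=0)
    density /= np.trapezoid(density, grid)
    return grid, density


def periodicity_spectrum(
    grid: np.ndarray,
    density: np.ndarray,
    search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
    pad_factor: int = 4,
) -> PeriodicityResult:
    """Power spectrum of the mean-subtracted density, on the periodicity axis.

    The density is zero-padded to ``pad_factor`` × its length before the DFT;
    power at frequency f is reported against periodicity 1/f molecules,
    restricted to ``search_range``.
    """
    grid = np.asarray(grid, dtype=float)
    density = np.asarray(density, dtype=float)
    steps = np.diff(grid)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("density grid must be uniform")
    step = float(steps[0])
    x = density - density.mean()
    n = pad_factor * x.size
    f = np.fft.rfftfreq(n, d=step)
    power = np.abs(np.fft.rfft(x, n=n)) ** 2
    pos = f > 0
    periodicity = 1.0 / f[pos]
    power = power[pos]
    lo, hi = search_range
    sel = (periodicity >= lo) & (periodicity <= hi)
    order = np.argsort(periodicity[sel])
    return PeriodicityResult(
        periodicity_grid=periodicity[sel][order],
        power=power[sel][order],
        search_range=(float(lo), float(hi)),
        meta={"grid_step": step, "n_fft": n},
    )


def _local_maxima(power: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima."""
    if power.size < 3:
        return np.array([], dtype=int)
    interior = (power[1:-1] > power[:-2]) & (power[1:-1] >= power[2:])
    return np.nonzero(interior)[0] + 1


def find_peak(
    result: PeriodicityResult,
    search_range: tuple[float, float] | None = None,
) -> tuple[float, float] | None:
    """Locate the dominant spectral peak and its half-width at half maximum.

    The peak is the largest *local* maximum of power within the search range
    (a global maximum sitting on a range edge is not a peak), refined by
    quadratic interpolation through the three surrounding points.  The HWHM is
    the mean of the left and right half-height crossings on the periodicity
    axis (one-sided if the other side is truncated).  Returns None — no-peak —
    for flat or edge-monotone spectra; the result object is updated in place.
    """
    per = result.periodicity_grid
    power = result.power
    if search_range is not None:
        sel = (per >= search_range[0]) & (per <= search_range[1])
        per, power = per[sel], power[sel]
    if per.size < 3 or np.allclose(power, power[0]):
        return None
    maxima = _local_maxima(power)
    if maxima.size == 0:
        return None
    i = int(maxima[np.argmax(power[maxima])])

    # quadratic refinement through three points on the periodicity axis
    a, b, _ = np.polyfit(per[i - 1 : i + 2], power[i - 1 : i + 2], 2)
    peak = float(-b / (2 * a)) if a < 0 else float(per[i])
    if not per[i - 1] <= peak <= per[i + 1]:
        peak = float(per[i])

    half = power[i] / 2.0
    left = right = None
    for j in range(i, 0, -1):
        if power[j - 1] < half:
            frac = (power[j] - half) / (power[j] - power[j - 1])
            left = peak - (per[j] - frac * (per[j] - per[j - 1]))
            break
    for j in range(i, per.size - 1):
        if power[j + 1] < half:
            frac = (power[j] - half) / (power[j] - power[j + 1])
            right = (per[j] + frac * (per[j + 1] - per[j])) - peak
            break
    widths = [w for w in (left, right) if w is not None and w > 0]
    hwhm = float(np.mean(widths)) if widths else float("nan")

    result.peak_periodicity = peak
    result.peak_hwhm = hwhm
    return peak, hwhm


def analyze_periodicity(
    values,
    bandwidth: float = DEFAULT_BANDWIDTH,
    search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
) -> PeriodicityResult:
    """KDE → power spectrum → peak finding in one call."""
    grid, density = stoichiometry_density(values, bandwidth=bandwidth)
    result = periodicity_spectrum(grid, density, search_range=search_range)
    find_peak(result)
    result.meta.update({"n_spots": int(np.asarray(values).size), "bandwidth": bandwidth})
    return result
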