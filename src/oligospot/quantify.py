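"""Image-to-intensity conversion: background estimation, elliptical Gaussian
spot fitting, single-fluorophore unit-intensity calibration and corrected
whole-cell integrated intensities.

The central quantity everywhere is integrated spot intensity in camera counts
above local background; dividing by the single-fluorophore unit intensity
converts it to a molecule count (see :mod:`oligospot.periodicity`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .containers import CameraModel, ImageStack

__all__ = [
    "CellROI",
    "GaussianFit",
    "UnitIntensity",
    "AutofluorescenceModel",
    "estimate_background",
    "fit_elliptical_gaussian",
    "is_single_step",
    "calibrate_unit_intensity",
    "fit_autofluorescence",
    "whole_cell_intensity",
]


@dataclass
class CellROI:
    """Rectangular cell region, half-open pixel bounds [row0:row1, col0:col1]."""

    row0: int
    col0: int
    row1: int
    col1: int
    cell_length_um: float
    constriction_class: str = "unconstricted"
    midcell_rc: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("ROI rectangle must be nonempty")
        if self.cell_length_um <= 0:
            raise ValueError("cell_length_um must be positive")

    def validate_in(self, shape: tuple[int, int]) -> None:
        if self.row0 < 0 or self.col0 < 0 or self.row1 > shape[0] or self.col1 > shape[1]:
            raise ValueError(f"ROI {self} outside image of shape {shape}")

    @property
    def n_pixels(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)


@dataclass
class GaussianFit:
    """Parameters of one fitted elliptical Gaussian spot.

    ``center`` is (x, y) in sub-pixel pixel-centre coordinates (x along
    columns).  ``integrated_intensity`` is the analytic volume of the Gaussian
    above the local offset: amplitude × 2π × σ_major × σ_minor.
    """

    center: tuple[float, float]
    sigma_major: float
    sigma_minor: float
    orientation: float
    amplitude: float
    local_offset: float
    integrated_intensity: float
    rss: float
    converged: bool
    no_spot: bool = False
    near_edge: bool = False


def _window_bounds(
    shape: tuple[int, int], seed_point: tuple[int, int], window: int
) -> tuple[int, int, int, int]:
    half = window // 2
    r0, c0 = seed_point[0] - half, seed_point[1] - half
    r1, c1 = r0 + window, c0 + window
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        raise ValueError(
            f"fit window {window}×{window} at {seed_point} extends outside image {shape}"
        )
    return r0, c0, r1, c1


def estimate_background(
    image: np.ndarray,
    roi: CellROI,
    exclusion: tuple[int, int, int, int] | None = None,
) -> float:
    """Median pixel value of the ROI, optionally excluding a sub-rectangle
    (typically the spot-fit window)."""
    image = np.asarray(image, dtype=float)
    roi.validate_in(image.shape)
    mask = np.zeros(image.shape, dtype=bool)
    mask[roi.row0 : roi.row1, roi.col0 : roi.col1] = True
    if exclusion is not None:
        r0, c0, r1, c1 = exclusion
        mask[r0:r1, c0:c1] = False
    if not mask.any():
        raise ValueError("no pixels left in ROI after exclusion")
    return float(np.median(image[mask]))


def _gaussian2d(coords, x0, y0, sx, sy, theta, amp, off):
    x, y = coords
    ct, st = math.cos(theta), math.sin(theta)
    u = ct * (x - x0) + st * (y - y0)
    v = -st * (x - x0) + ct * (y - y0)
    return off + amp * np.exp(-0.5 * (u / sx) ** 2 - 0.5 * (v / sy) ** 2)


def fit_elliptical_gaussian(
    image: np.ndarray,
    seed_point: tuple[int, int],
    window: int = 9,
    background: float | None = None,
    rotated: bool = True,
    fixed_sigma: float | None = None,
) -> GaussianFit:
    """Nonlinear least-squares fit of an elliptical Gaussian plus flat offset.

    The fit runs over a ``window``×``window`` region centred on ``seed_point``
    (row, col).  Orientation is a free parameter reported in [0, π) unless
    ``rotated=False`` (axis-aligned fit).  With ``fixed_sigma`` (pixels) the
    shape is pinned to a circular Gaussian of that width and only position,
    amplitude and offset are fitted — appropriate for dim single fluorophores
    whose ellipticity is not constrained by the data.  A nonpositive amplitude
    at the optimum is flagged ``no_spot``; centres within 3 σ_major of the
    window edge are flagged ``near_edge``.
    """
    image = np.asarray(image, dtype=float)
    r0, c0, r1, c1 = _window_bounds(image.shape, tuple(seed_point), window)
    data = image[r0:r1, c0:c1]
    ys, xs = np.mgrid[r0:r1, c0:c1]
    x = xs.ravel().astype(float)
    y = ys.ravel().astype(float)
    z = data.ravel()

    off0 = float(background) if background is not None else float(np.median(z))
    amp0 = max(float(z.max() - off0), 0.0)
    # moment-based initialization
    w = np.clip(z - off0, 0.0, None)
    if w.sum() > 0 and amp0 > 0:
        xbar = float((w * x).sum() / w.sum())
        ybar = float((w * y).sum() / w.sum())
        vxx = float((w * (x - xbar) ** 2).sum() / w.sum())
        vyy = float((w * (y - ybar) ** 2).sum() / w.sum())
        vxy = float((w * (x - xbar) * (y - ybar)).sum() / w.sum())
        cov = np.array([[max(vxx, 0.1), vxy], [vxy, max(vyy, 0.1)]])
        evals, evecs = np.linalg.eigh(cov)
        sx0 = float(np.sqrt(max(evals[1], 0.25)))
        sy0 = float(np.sqrt(max(evals[0], 0.25)))
        th0 = float(math.atan2(evecs[1, 1], evecs[0, 1]))
    else:
        xbar, ybar = (c0 + c1 - 1) / 2.0, (r0 + r1 - 1) / 2.0
        sx0 = sy0 = 1.5
        th0 = 0.0

    if fixed_sigma is not None:
        s = float(fixed_sigma)
        p0 = [xbar, ybar, amp0, off0]

        def resid(p):
            return _gaussian2d((x, y), p[0], p[1], s, s, 0.0, p[2], p[3]) - z

        lb = [c0 - 1, r0 - 1, 0.0, -np.inf]
        ub = [c1, r1, np.inf, np.inf]
    elif rotated:
        p0 = [xbar, ybar, sx0, sy0, th0, amp0, off0]

        def resid(p):
            return _gaussian2d((x, y), *p) - z

        lb = [c0 - 1, r0 - 1, 0.3, 0.3, -2 * math.pi, 0.0, -np.inf]
        ub = [c1, r1, float(window), float(window), 2 * math.pi, np.inf, np.inf]
    else:
        p0 = [xbar, ybar, sx0, sy0, amp0, off0]

        def resid(p):
            return _gaussian2d((x, y), p[0], p[1], p[2], p[3], 0.0, p[4], p[5]) - z

        lb = [c0 - 1, r0 - 1, 0.3, 0.3, 0.0, -np.inf]
        ub = [c1, r1, float(window), float(window), np.inf, np.inf]

    result = optimize.least_squares(resid, p0, bounds=(lb, ub), method="trf")
    p = result.x
    if fixed_sigma is not None:
        x0, y0, amp, off = p
        sx = sy = float(fixed_sigma)
        theta = 0.0
    elif rotated:
        x0, y0, sx, sy, theta, amp, off = p
    else:
        x0, y0, sx, sy, amp, off = p
        theta = 0.0
    if sy > sx:
        sx, sy = sy, sx
        theta += math.pi / 2
    theta = float(theta % math.pi)
    integrated = float(amp * 2 * math.pi * sx * sy)
    no_spot = amp <= max(1e-12, 1e-9 * abs(off))
    edge_dist = min(x0 - c0, c1 - 1 - x0, y0 - r0, r1 - 1 - y0)
    return GaussianFit(
        center=(float(x0), float(y0)),
        sigma_major=float(sx),
        sigma_minor=float(sy),
        orientation=theta,
        amplitude=float(amp),
        local_offset=float(off),
        integrated_intensity=integrated,
        rss=float(np.sum(result.fun**2)),
        converged=bool(result.success),
        no_spot=bool(no_spot),
        near_edge=bool(edge_dist < 3 * sx),
    )


def _segment_rss(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """RSS of the constant fit to trace[i:j] from prefix sums."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return s2 - s * s / n


def is_single_step(trace: np.ndarray, min_segment: int = 2) -> bool:
    """True if an intensity trace is best described by one downward step.

    Compares piecewise-constant models with zero, one and two changepoints by
    BIC (exhaustive changepoint search); accepts only when the one-step model
    wins and the step is downward.  Used to validate calibration spots as
    single fluorophores (one-step disappearance).
    """
    z = np.asarray(trace, dtype=float)
    n = z.size
    if n < 2 * min_segment:
        return False
    prefix = np.concatenate([[0.0], np.cumsum(z)])
    prefix2 = np.concatenate([[0.0], np.cumsum(z**2)])

    def bic(rss: float, n_params: int) -> float:
        return n * math.log(rss / n + 1e-12) + n_params * math.log(n)

    bic0 = bic(_segment_rss(prefix, prefix2, 0, n), 1)

    best1, best1_cp = np.inf, None
    for cp in range(min_segment, n - min_segment + 1):
        rss = _segment_rss(prefix, prefix2, 0, cp) + _segment_rss(prefix, prefix2, cp, n)
        if rss < best1:
            best1, best1_cp = rss, cp
    bic1 = bic(best1, 3)

    best2 = np.inf
    for cp1 in range(min_segment, n - 2 * min_segment + 1):
        for cp2 in range(cp1 + min_segment, n - min_segment + 1):
            rss = (
                _segment_rss(prefix, prefix2, 0, cp1)
                + _segment_rss(prefix, prefix2, cp1, cp2)
                + _segment_rss(prefix, prefix2, cp2, n)
            )
            if rss < best2:
                best2 = rss
    bic2 = bic(best2, 5) if np.isfinite(best2) else np.inf

    if not (bic1 < bic0 and bic1 <= bic2):
        return False
    before = z[:best1_cp].mean()
    after = z[best1_cp:].mean()
    return after < before


@dataclass
class UnitIntensity:
    """Mean integrated intensity of a single fluorophore, in counts."""

    mean: float
    se: float
    n_spots: int

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("unit intensity must be positive")
        if self.se < 0:
            raise ValueError("se must be nonnegative")


def calibrate_unit_intensity(spot_intensities) -> UnitIntensity:
    """Mean ± SE of validated single-fluorophore spot intensities.

    Warns when the coefficient of variation exceeds 0.5, which usually means
    the input mixes single and multiple fluorophores.
    """
    values = np.asarray(list(spot_intensities), dtype=float)
    if values.size == 0:
        raise ValueError("no spot intensities supplied")
    mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(values.size)) if values.size > 1 else 0.0
    if mean > 0 and values.size > 1 and values.std(ddof=1) / mean > 0.5:
        warnings.warn(
            "coefficient of variation > 0.5: input may not be single fluorophores",
            stacklevel=2,
        )
    return UnitIntensity(mean=mean, se=se, n_spots=int(values.size))


@dataclass
class AutofluorescenceModel:
    """Linear model of whole-cell autofluorescence vs cell length."""

    slope: float  # counts per µm
    intercept: float  # counts
    slope_se: float = 0.0

    def predict(self, cell_length_um) -> np.ndarray | float:
        return self.slope * np.asarray(cell_length_um, dtype=float) + self.intercept


def fit_autofluorescence(cell_lengths_um, intensities) -> AutofluorescenceModel:
    """Ordinary least-squares line of corrected intensity vs cell length,
    fitted on unlabelled (wild-type) cells."""
    lengths = np.asarray(cell_lengths_um, dtype=float)
    values = np.asarray(intensities, dtype=float)
    if lengths.size != values.size:
        raise ValueError("length/intensity arrays must match")
    if np.unique(lengths).size < 2:
        raise ValueError("need at least two distinct cell lengths")
    fit = stats.linregress(lengths, values)
    model = AutofluorescenceModel(
        slope=float(fit.slope), intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
    )
    if np.any(np.asarray(model.predict(lengths)) < 0):
        warnings.warn("autofluorescence prediction negative over fitted range",
                      stacklevel=2)
    return model


def whole_cell_intensity(
    image: np.ndarray | ImageStack,
    roi: CellROI,
    autofluor: AutofluorescenceModel | None,
    camera: CameraModel,
    frame: int = 0,
) -> float:
    """Integrated counts over the cell rectangle, corrected for camera offset
    and cell autofluorescence.

    May legitimately be negative for empty cells (pure noise); the value is
    reported as-is.
    """
    if isinstance(image, ImageStack):
        img = image.counts[frame]
    else:
        img = np.asarray(image, dtype=float)
        if img.ndim == 3:
            img = img[frame]
    roi.validate_in(img.shape)
    total = float(img[roi.row0 : roi.row1, roi.col0 : roi.col1].sum())
    corrected = total - camera.offset * roi.n_pixels
    if autofluor is not None:
        corrected -= float(autofluor.predict(roi.cell_length_um))
    return corrected
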