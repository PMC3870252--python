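"""Photobleaching models: single-exponential survival fitting, binomial
thinning of stoichiometries (the 50%-bleach control) and extrapolation of
copy numbers to time zero.

Irreversible single-step bleaching of independent fluorophores gives an
exponential ensemble survival S(t) = exp(-rate·t); partial bleaching of a
spot of n molecules leaves Binomial(n, p) visible, so the expected count
after 50% bleaching of a hexamer is exactly 3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import PhotophysicsMatrix

__all__ = [
    "BleachModel",
    "fit_bleach_decay",
    "survival_curve",
    "binomial_thin",
    "extrapolate_initial_count",
]


@dataclass
class BleachModel:
    """Single-exponential photobleaching: survival(t) = exp(-rate·t).

    ``rate`` is in inverse units of the time axis used for the fit (per frame
    or per second).
    """

    rate: float
    rate_se: float = 0.0
    rss: float = 0.0
    n: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("bleach rate must be nonnegative")

    def survival(self, t) -> np.ndarray | float:
        return np.exp(-self.rate * np.asarray(t, dtype=float))


def survival_curve(states: PhotophysicsMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(frame index, surviving fraction) from a simulated photophysics matrix."""
    return np.arange(states.n_frames), states.surviving_fraction()


def fit_bleach_decay(times, surviving_fraction) -> BleachModel:
    """Weighted log-linear fit of exp(-rate·t) through survival data.

    The fit is linear in log space, constrained through survival(0) = 1, with
    inverse-variance weights w ∝ f/(1−f) appropriate for binomially counted
    surviving fractions.  An increasing series triggers a warning and the fit
    proceeds; a negative fitted rate is clipped to zero (with a warning).
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(surviving_fraction, dtype=float)
    if t.size != f.size:
        raise ValueError("times and fractions must have equal length")
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("surviving fractions must be in (0, 1]")
    if np.any(np.diff(f) > 0):
        warnings.warn("surviving fraction increases somewhere; fit proceeds",
                      stacklevel=2)

    y = np.log(f)
    w = f / np.clip(1.0 - f, 1e-9, None)
    w = np.minimum(w, 1e6)
    denom = float(np.sum(w * t * t))
    if denom == 0:
        return BleachModel(rate=0.0, n=t.size)
    rate = float(-np.sum(w * t * y) / denom)
    resid = y + rate * t
    rss = float(np.sum(w * resid**2))
    dof = max(t.size - 1, 1)
    rate_se = math.sqrt(max(rss / dof, 0.0) / denom)
    if rate < 0:
        warnings.warn("fitted bleach rate was negative; clipped to 0", stacklevel=2)
        rate = 0.0
    return BleachModel(rate=rate, rate_se=rate_se, rss=rss, n=int(t.size))


def binomial_thin(
    stoichiometries,
    survive_p: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Thin each molecule independently with survival probability p.

    Real-valued stoichiometries are rounded to the nearest integer first
    (thinning is defined on molecules); the output per spot is
    Binomial(n_i, p).
    """
    if not 0.0 <= survive_p <= 1.0:
        raise ValueError("survive_p must be in [0, 1]")
    counts = np.rint(np.asarray(stoichiometries, dtype=float)).astype(int)
    if np.any(counts < 0):
        raise ValueError("stoichiometries must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.binomial(counts, survive_p)


def extrapolate_initial_count(
    observed_count,
    model: BleachModel,
    elapsed,
    return_se: bool = False,
):
    """Extrapolate an observed copy number back to time zero, before bleaching.

    Returns observed / survival(elapsed); e.g. 5 molecules remaining after
    92.2% bleaching (survival 0.078) extrapolate to 64.10.  With
    ``return_se=True`` the uncertainty propagated from the fitted rate SE is
    returned as well.
    """
    s = model.survival(elapsed)
    if np.any(np.asarray(s) < 1e-9):
        raise ValueError(
            "survival underflow: elapsed time too large for a reliable extrapolation"
        )
    initial = np.asarray(observed_count, dtype=float) / s
    if np.ndim(observed_count) == 0:
        initial = float(initial)
    if not return_se:
        return initial
    # d(initial)/d(rate) = initial * elapsed
    se = np.abs(initial) * np.asarray(elapsed, dtype=float) * model.rate_se
    if np.ndim(observed_count) == 0:
        se = float(se)
    return initial, se
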