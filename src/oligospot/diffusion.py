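"""Single-particle tracking and diffusion analysis.

Per-frame spot detection (local maxima above a noise threshold, refined by
the elliptical Gaussian fit), greedy nearest-neighbour linking, time- and
ensemble-averaged mean-square displacement, and diffusion-coefficient
estimation from the initial linear regime: for free 2-D Brownian motion
MSD(τ) = 4 D τ + 4 σ_loc², so D is the slope of the first few lag points
divided by 4, with the free intercept absorbing localization error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.feature import peak_local_max

from .containers import ImageStack, Track, TrackSet
from .quantify import fit_elliptical_gaussian

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "detect_per_frame",
    "link_nearest_neighbour",
    "ensemble_msd",
    "estimate_D",
]

#: |D| below this (µm²/s) is reported as near-immobile.
IMMOBILE_THRESHOLD = 1e-3

#: Prior D (µm²/s) used for the default linking search radius
#: max_disp = 3·sqrt(4·D_prior·dt).
D_PRIOR = 0.1


@dataclass
class MSDCurve:
    """Ensemble mean-square displacement per lag time."""

    lag_times_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lag_times_s = np.asarray(self.lag_times_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(self.msd_um2 < 0):
            raise ValueError("msd must be nonnegative")

    def __len__(self) -> int:
        return self.lag_times_s.size


@dataclass
class DiffusionEstimate:
    """Apparent diffusion coefficient from the initial MSD slope."""

    d_um2_s: float
    intercept_um2: float
    se_d: float
    n_points_fit: int
    near_immobile: bool


def detect_per_frame(
    stack: ImageStack,
    threshold_sd: float = 5.0,
    min_distance: int = 3,
    fit_window: int = 7,
) -> pd.DataFrame:
    """Detect sub-pixel spot positions in every frame.

    Candidates are local maxima exceeding the frame background (median) by
    ``threshold_sd`` robust noise standard deviations, then refined by an
    elliptical Gaussian fit over ``fit_window`` pixels.  Returns a table with
    columns frame, row, col, x_um, y_um, intensity; the integrated intensity
    allows downstream classification of monomer vs dimer spots.
    """
    px = stack.pixel_size_um
    rows = []
    half = fit_window // 2
    for t in range(stack.n_frames):
        frame = stack.counts[t]
        background = float(np.median(frame))
        noise_sd = 1.4826 * float(np.median(np.abs(frame - background)))
        if noise_sd == 0:
            noise_sd = float(frame.std()) or 1.0
        coords = peak_local_max(
            frame,
            min_distance=min_distance,
            threshold_abs=background + threshold_sd * noise_sd,
            exclude_border=half,
        )
        for r, c in coords:
            fit = fit_elliptical_gaussian(
                frame, (int(r), int(c)), window=fit_window, background=background
            )
            if fit.no_spot or not fit.converged:
                continue
            x_px, y_px = fit.center
            rows.append(
                {
                    "frame": t,
                    "row": y_px,
                    "col": x_px,
                    "x_um": (x_px + 0.5) * px,
                    "y_um": (y_px + 0.5) * px,
                    "intensity": fit.integrated_intensity,
                }
            )
    return pd.DataFrame(
        rows, columns=["frame", "row", "col", "x_um", "y_um", "intensity"]
    )


def link_nearest_neighbour(
    detections: pd.DataFrame,
    max_disp_um: float | None = None,
    max_gap: int = 0,
    dt_s: float = 0.01,
) -> TrackSet:
    """Greedy nearest-neighbour linking of per-frame detections into tracks.

    Candidate (track, detection) pairs within ``max_disp_um`` are assigned in
    ascending order of distance (ties broken by detection index, then track
    index); unmatched detections start new tracks and tracks missing for more
    than ``max_gap`` consecutive frames are terminated.  No detection is used
    twice.  The default search radius is 3·sqrt(4·D_prior·dt) with
    D_prior = 0.1 µm²/s.
    """
    if max_disp_um is None:
        max_disp_um = 3.0 * math.sqrt(4.0 * D_PRIOR * dt_s)
    if max_disp_um <= 0:
        raise ValueError("max_disp_um must be positive")
    required = {"frame", "x_um", "y_um"}
    if not required.issubset(detections.columns):
        raise ValueError(f"detections table needs columns {sorted(required)}")

    active: list[dict] = []  # each: {'frames': [...], 'pos': [...], 'last': (x,y)}
    finished: list[dict] = []
    for frame in range(
        int(detections["frame"].min()) if len(detections) else 0,
        int(detections["frame"].max()) + 1 if len(detections) else 0,
    ):
        dets = detections[detections["frame"] == frame]
        points = dets[["x_um", "y_um"]].to_numpy(dtype=float)

        # retire stale tracks
        still = []
        for tr in active:
            if frame - tr["frames"][-1] > max_gap + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still

        pairs = []
        for ti, tr in enumerate(active):
            last = np.asarray(tr["pos"][-1])
            d = np.hypot(points[:, 0] - last[0], points[:, 1] - last[1])
            for di in np.nonzero(d <= max_disp_um)[0]:
                pairs.append((float(d[di]), int(di), ti))
        pairs.sort()
        used_det: set[int] = set()
        used_track: set[int] = set()
        for dist, di, ti in pairs:
            if di in used_det or ti in used_track:
                continue
            used_det.add(di)
            used_track.add(ti)
            active[ti]["frames"].append(frame)
            active[ti]["pos"].append(points[di])
        for di in range(points.shape[0]):
            if di not in used_det:
                active.append({"frames": [frame], "pos": [points[di]]})
    finished.extend(active)

    tracks = [
        Track(
            frames=np.asarray(tr["frames"]),
            positions_um=np.asarray(tr["pos"]),
            track_id=i,
        )
        for i, tr in enumerate(finished)
    ]
    return TrackSet(tracks=tracks, dt_s=dt_s)


def ensemble_msd(tracks: TrackSet, max_lag: int = 10) -> MSDCurve:
    """Time- and ensemble-averaged MSD over all ordered frame pairs per lag.

    Per lag, every pair of positions separated by exactly that many frames
    contributes one squared displacement; track averages are pooled weighted
    by their pair counts (a single pooled mean).
    """
    usable = [t for t in tracks if len(t) >= 2]
    if not usable:
        raise ValueError("no tracks with at least 2 points")
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for track in usable:
        frames = track.frames
        pos = track.positions_um
        index = {int(f): i for i, f in enumerate(frames)}
        for lag in range(1, max_lag + 1):
            for f, i in index.items():
                j = index.get(f + lag)
                if j is not None:
                    d = pos[j] - pos[i]
                    sums[lag - 1] += float(d @ d)
                    counts[lag - 1] += 1
    valid = counts > 0
    lags = np.arange(1, max_lag + 1)[valid]
    return MSDCurve(
        lag_times_s=lags * tracks.dt_s,
        msd_um2=sums[valid] / counts[valid],
        n_pairs=counts[valid],
    )


def estimate_D(msd: MSDCurve, n_points: int = 4) -> DiffusionEstimate:
    """Diffusion coefficient from an OLS fit of the first ``n_points`` lags.

    D = slope / 4 (2-D motion in the image plane), with a free intercept that
    absorbs the localization-error offset 4 σ_loc².  A negative slope is
    reported with its sign; |D| < 1e-3 µm²/s is flagged near-immobile.
    """
    if n_points < 2:
        raise ValueError("need at least 2 points for the fit")
    if len(msd) < n_points:
        raise ValueError(f"MSD curve has {len(msd)} lags, need {n_points}")
    t = msd.lag_times_s[:n_points]
    y = msd.msd_um2[:n_points]
    fit = stats.linregress(t, y)
    d = float(fit.slope) / 4.0
    return DiffusionEstimate(
        d_um2_s=d,
        intercept_um2=float(fit.intercept),
        se_d=float(fit.stderr) / 4.0 if np.isfinite(fit.stderr) else float("nan"),
        n_points_fit=n_points,
        near_immobile=bool(abs(d) < IMMOBILE_THRESHOLD),
    )
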