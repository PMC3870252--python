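"""Shared data containers used by both the simulator and the analysis modules.

These are deliberately thin: plain dataclasses wrapping numpy arrays plus the
acquisition metadata (pixel size, frame interval, camera model) that every
downstream computation needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CameraModel", "ImageStack", "Track", "TrackSet"]


@dataclass(frozen=True)
class CameraModel:
    """sCMOS camera forward model: counts = offset + read noise + photons/gain.

    Parameters
    ----------
    offset:
        Constant camera offset, in counts.
    gain:
        Photons per count (conversion factor applied after shot noise).
    read_noise_sd:
        Standard deviation of the additive Gaussian read noise, in counts.
    pixel_size_um:
        Back-projected pixel size in the sample plane, in micrometres.
    """

    offset: float = 100.0
    gain: float = 2.0
    read_noise_sd: float = 2.0
    pixel_size_um: float = 0.08

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"gain must be positive, got {self.gain}")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be nonnegative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class ImageStack:
    """A multi-frame fluorescence image in camera counts.

    ``counts`` has shape ``(n_frames, n_rows, n_cols)``.  The x image axis maps
    to columns and y to rows; a continuous position ``x`` µm falls in column
    ``x / pixel_size_um`` with pixel centres at half-integer multiples.
    """

    counts: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    camera: CameraModel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim == 2:
            self.counts = self.counts[None]
        if self.counts.ndim != 3:
            raise ValueError("counts must be (frames, rows, cols)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.counts.shape[1:]


@dataclass
class Track:
    """One linked single-particle trajectory.

    ``frames`` are strictly increasing integer frame indices (gaps allowed);
    ``positions_um`` is the matching ``(n, 2)`` array of (x, y) positions.
    ``true_positions_um`` is only set by the simulator (noise-free ground truth).
    """

    frames: np.ndarray
    positions_um: np.ndarray
    region: str = "noncentral"
    track_id: int = -1
    true_positions_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.positions_um.shape != (self.frames.size, 2):
            raise ValueError("positions_um must be (n_frames, 2)")
        if self.frames.size > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return self.frames.size


@dataclass
class TrackSet:
    """A collection of trajectories sharing one frame interval.

    When produced by the simulator, the ground-truth diffusion coefficient and
    localization error are carried along for parameter-recovery checks.
    """

    tracks: list[Track]
    dt_s: float
    true_d_um2_s: float | None = None
    loc_sigma_um: float | None = None

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)
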