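"""Synthetic single-molecule microscopy data with known ground truth.

This module emulates the acquisition regime of live-cell single-molecule
counting experiments on rod-shaped bacteria: membrane-bound monomeric
fluorophores diffusing over the projected cell outline, diffraction-limited
midcell clusters built from an oligomeric unit (hexamers by default),
irreversible per-fluorophore photobleaching, 2-D Gaussian PSF rendering and an
sCMOS camera noise model (offset + Gaussian read noise + Poisson shot noise).

Everything is driven by explicit integer seeds so that any downstream analysis
can be validated against exact ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .containers import CameraModel, ImageStack, Track, TrackSet

logger = logging.getLogger(__name__)

__all__ = [
    "FILAMENT_LENGTH_UM",
    "CONSTRICTION_CLASSES",
    "CellModel",
    "EmitterSet",
    "PhotophysicsMatrix",
    "SimulationConfig",
    "build_cell_model",
    "sample_emitters",
    "simulate_bleaching",
    "render_stack",
    "simulate_tracks",
    "simulate_confined_tracks",
    "simulate_midcell_stoichiometries",
]

#: Cells longer than this are classified as filaments.
FILAMENT_LENGTH_UM = 9.0

CONSTRICTION_CLASSES = ("unconstricted", "constricted", "filament")

#: Default copies-of-the-oligomeric-unit per midcell cluster, by constriction
#: class: one to three units before visible constriction, four to seven early
#: in constriction; filaments may carry the full range.
DEFAULT_UNITS_RANGE = {
    "unconstricted": (1, 3),
    "constricted": (4, 7),
    "filament": (1, 7),
}


@dataclass(frozen=True)
class CellModel:
    """2-D projected rod-shaped cell: a rectangle with hemispherical caps.

    The outline is the boundary of a stadium of total length ``length_um`` and
    width ``width_um``; the membrane band is a ring of width ``band`` around
    that outline.  Positions are in micrometres in the image frame.
    """

    length_um: float
    width_um: float
    center_um: tuple[float, float] = (0.0, 0.0)
    axis_angle_rad: float = 0.0
    constriction_class: str = "unconstricted"

    def __post_init__(self) -> None:
        if not (self.length_um > self.width_um > 0):
            raise ValueError(
                f"need length > width > 0, got length={self.length_um}, "
                f"width={self.width_um}"
            )
        if self.constriction_class not in CONSTRICTION_CLASSES:
            raise ValueError(f"unknown constriction class {self.constriction_class!r}")
        is_filament = self.length_um > FILAMENT_LENGTH_UM
        if is_filament != (self.constriction_class == "filament"):
            raise ValueError(
                f"constriction class {self.constriction_class!r} inconsistent with "
                f"length {self.length_um} µm (filament iff length > "
                f"{FILAMENT_LENGTH_UM} µm)"
            )

    # -- geometry -------------------------------------------------------
    @property
    def _half_axis(self) -> float:
        """Half-length of the straight section of the long axis."""
        return (self.length_um - self.width_um) / 2.0

    @property
    def _cap_radius(self) -> float:
        return self.width_um / 2.0

    def to_cell_frame(self, points_um: np.ndarray) -> np.ndarray:
        """Rotate/translate lab-frame (x, y) µm points into the cell frame
        (long axis along +x, origin at the cell centre)."""
        p = np.atleast_2d(np.asarray(points_um, dtype=float)) - np.asarray(self.center_um)
        c, s = math.cos(-self.axis_angle_rad), math.sin(-self.axis_angle_rad)
        rot = np.array([[c, -s], [s, c]])
        return p @ rot.T

    def to_lab_frame(self, points_um: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        c, s = math.cos(self.axis_angle_rad), math.sin(self.axis_angle_rad)
        rot = np.array([[c, -s], [s, c]])
        return p @ rot.T + np.asarray(self.center_um)

    def boundary_distance(self, points_um: np.ndarray) -> np.ndarray:
        """Signed distance (µm) to the cell outline; negative inside."""
        p = self.to_cell_frame(points_um)
        a, r = self._half_axis, self._cap_radius
        dx = np.maximum(np.abs(p[:, 0]) - a, 0.0)
        return np.hypot(dx, p[:, 1]) - r

    def contains(self, points_um: np.ndarray, band_um: float = 0.1) -> np.ndarray:
        """True for points inside the cell or within the membrane band."""
        return self.boundary_distance(points_um) <= band_um / 2.0

    def in_membrane_band(self, points_um: np.ndarray, band_um: float = 0.1) -> np.ndarray:
        return np.abs(self.boundary_distance(points_um)) <= band_um / 2.0

    def sample_membrane_points(
        self, n: int, rng: np.random.Generator, band_um: float = 0.1
    ) -> np.ndarray:
        """Sample ``n`` points uniformly over the projected membrane outline
        band (uniform in arclength, uniform normal offset within the band)."""
        a, r = self._half_axis, self._cap_radius
        perimeter = 4 * a + 2 * math.pi * r
        s = rng.uniform(0.0, perimeter, size=n)
        u = rng.uniform(-band_um / 2.0, band_um / 2.0, size=n)
        pts = np.empty((n, 2))
        for i, (si, ui) in enumerate(zip(s, u)):
            if si < 2 * a:  # top edge
                base = np.array([si - a, r])
                normal = np.array([0.0, 1.0])
            elif si < 4 * a:  # bottom edge
                base = np.array([(si - 2 * a) - a, -r])
                normal = np.array([0.0, -1.0])
            else:  # caps, right then left
                phi = (si - 4 * a) / r  # 0..2π
                theta = phi - math.pi / 2  # right cap -π/2..π/2, left π/2..3π/2
                centre = np.array([a if phi < math.pi else -a, 0.0])
                normal = np.array([math.cos(theta), math.sin(theta)])
                base = centre + r * normal
            pts[i] = base + ui * normal
        return self.to_lab_frame(pts)


def build_cell_model(
    length_um: float,
    width_um: float,
    constriction_class: str | None = None,
    center_um: tuple[float, float] = (0.0, 0.0),
    axis_angle_rad: float = 0.0,
) -> CellModel:
    """Construct a :class:`CellModel`, enforcing the filament length rule.

    Cells longer than 9 µm are classified as filaments regardless of the class
    passed in; shorter cells default to "unconstricted".  Geometry is fully
    deterministic for given inputs.
    """
    if length_um > FILAMENT_LENGTH_UM:
        cls = "filament"
    elif constriction_class == "filament":
        raise ValueError(
            f"length {length_um} µm ≤ {FILAMENT_LENGTH_UM} µm cannot be a filament"
        )
    else:
        cls = constriction_class or "unconstricted"
    return CellModel(
        length_um=length_um,
        width_um=width_um,
        center_um=tuple(center_um),
        axis_angle_rad=axis_angle_rad,
        constriction_class=cls,
    )


@dataclass
class EmitterSet:
    """Ground-truth fluorophore positions for one cell.

    ``cluster_id`` is 0 for noncentral monomers and ``>= 1`` for midcell
    clusters; every cluster holds an exact multiple of ``oligomer_size``
    emitters, all colocalized below the diffraction limit.
    """

    positions_um: np.ndarray
    cluster_id: np.ndarray
    oligomer_size: int = 6
    photon_rate: float = 400.0
    cell: CellModel | None = None

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float).reshape(-1, 2)
        self.cluster_id = np.asarray(self.cluster_id, dtype=int)
        if self.cluster_id.shape != (self.positions_um.shape[0],):
            raise ValueError("cluster_id must match number of emitters")
        for cid in np.unique(self.cluster_id):
            if cid > 0 and (self.cluster_id == cid).sum() % self.oligomer_size:
                raise ValueError(
                    f"cluster {cid} size is not a multiple of {self.oligomer_size}"
                )

    @property
    def n_emitters(self) -> int:
        return self.positions_um.shape[0]

    def cluster_units(self) -> dict[int, int]:
        """Copies of the oligomeric unit per midcell cluster id."""
        return {
            int(cid): int((self.cluster_id == cid).sum() // self.oligomer_size)
            for cid in np.unique(self.cluster_id)
            if cid > 0
        }


def sample_emitters(
    cell: CellModel,
    n_monomers: int,
    n_clusters: int,
    oligomer_size: int = 6,
    photon_rate: float = 400.0,
    seed: int | np.random.Generator | None = None,
    units_range: tuple[int, int] | None = None,
    band_um: float = 0.1,
) -> EmitterSet:
    """Place monomers on the membrane outline and oligomer clusters at midcell.

    Monomers (``cluster_id == 0``) are uniform over the projected membrane
    band.  Each of the ``n_clusters`` midcell clusters is a single point
    source of ``k × oligomer_size`` colocalized emitters, with ``k`` drawn
    uniformly from ``units_range`` (default depends on the cell's constriction
    class).  Clusters sit on the membrane outline within ±0.5 × width of the
    cell centre along the long axis.
    """
    if n_monomers < 0 or n_clusters < 0:
        raise ValueError("emitter counts must be nonnegative")
    if oligomer_size < 1:
        raise ValueError("oligomer_size must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if units_range is None:
        units_range = DEFAULT_UNITS_RANGE[cell.constriction_class]
    lo, hi = units_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid units_range {units_range}")

    positions = [cell.sample_membrane_points(n_monomers, rng, band_um)]
    ids = [np.zeros(n_monomers, dtype=int)]
    a, r = cell._half_axis, cell._cap_radius
    for j in range(1, n_clusters + 1):
        k = int(rng.integers(lo, hi + 1))
        dx = rng.uniform(-0.5 * cell.width_um, 0.5 * cell.width_um)
        dx = float(np.clip(dx, -a, a)) if a > 0 else 0.0
        side = 1.0 if rng.random() < 0.5 else -1.0
        dy = side * (r + rng.uniform(-band_um / 2.0, band_um / 2.0))
        point = cell.to_lab_frame(np.array([[dx, dy]]))[0]
        n_emit = k * oligomer_size
        positions.append(np.tile(point, (n_emit, 1)))
        ids.append(np.full(n_emit, j, dtype=int))
    return EmitterSet(
        positions_um=np.vstack(positions),
        cluster_id=np.concatenate(ids),
        oligomer_size=oligomer_size,
        photon_rate=photon_rate,
        cell=cell,
    )


@dataclass
class PhotophysicsMatrix:
    """Per-frame emitting/bleached state for every emitter.

    ``states`` has shape ``(n_frames, n_emitters)``; bleaching is irreversible
    so every column is monotonically nonincreasing.  The expected surviving
    fraction at frame ``t`` is ``(1 - bleach_rate) ** t``.
    """

    states: np.ndarray
    bleach_rate: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.ndim != 2:
            raise ValueError("states must be (n_frames, n_emitters)")
        if np.any(np.diff(self.states.astype(int), axis=0) > 0):
            raise ValueError("bleaching must be irreversible")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    def surviving_fraction(self) -> np.ndarray:
        return self.states.mean(axis=1)


def simulate_bleaching(
    emitters: EmitterSet | int,
    bleach_rate: float,
    n_frames: int,
    seed: int | np.random.Generator | None = None,
) -> PhotophysicsMatrix:
    """Irreversible single-step photobleaching, one Bernoulli trial per frame.

    Every emitter is emitting in frame 0 and bleaches independently with
    per-frame probability ``bleach_rate`` at each subsequent frame transition.
    """
    if not 0.0 <= bleach_rate <= 1.0:
        raise ValueError("bleach_rate must be in [0, 1]")
    n = emitters if isinstance(emitters, int) else emitters.n_emitters
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    survive = rng.random((max(n_frames - 1, 0), n)) >= bleach_rate
    states = np.ones((n_frames, n), dtype=bool)
    if n_frames > 1:
        states[1:] = np.cumprod(survive, axis=0).astype(bool)
    return PhotophysicsMatrix(states=states, bleach_rate=bleach_rate)


def _psf_patch(
    pos_um: np.ndarray,
    photons: float,
    psf_sigma_um: float,
    pixel_size_um: float,
    shape: tuple[int, int],
) -> tuple[slice, slice, np.ndarray] | None:
    """Center-sampled 2-D Gaussian PSF patch for one emitter, clipped to the
    field of view.  Returns (row slice, col slice, photon image) or None."""
    sigma_px = psf_sigma_um / pixel_size_um
    # pixel-centre coordinates of the emitter
    cx = pos_um[0] / pixel_size_um - 0.5
    cy = pos_um[1] / pixel_size_um - 0.5
    half = int(math.ceil(5 * sigma_px))
    r0 = max(int(math.floor(cy)) - half, 0)
    r1 = min(int(math.floor(cy)) + half + 1, shape[0])
    c0 = max(int(math.floor(cx)) - half, 0)
    c1 = min(int(math.floor(cx)) + half + 1, shape[1])
    if r0 >= r1 or c0 >= c1:
        return None
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    gy = np.exp(-0.5 * ((rows - cy) / sigma_px) ** 2)
    gx = np.exp(-0.5 * ((cols - cx) / sigma_px) ** 2)
    patch = photons / (2 * math.pi * sigma_px**2) * np.outer(gy, gx)
    return slice(r0, r1), slice(c0, c1), patch


def render_stack(
    emitters: EmitterSet | list[EmitterSet],
    states: PhotophysicsMatrix | None,
    cells: CellModel | list[CellModel] | None = None,
    psf_sigma_um: float = 0.12,
    camera: CameraModel | None = None,
    shape: tuple[int, int] | None = None,
    autofluor_photons_per_um: float = 0.0,
    seed: int | np.random.Generator | None = None,
    shot_noise: bool = True,
    frame_interval_s: float = 0.0175,
) -> ImageStack:
    """Render emitters into a multi-frame camera-count image stack.

    Per pixel and frame, counts = offset + Gaussian read noise +
    Poisson(signal + autofluorescence) / gain.  With ``shot_noise=False`` and
    a zero-read-noise camera the rendering is exactly deterministic and the
    background-subtracted count sum equals (number emitting × photon rate) /
    gain, up to PSF truncation at 5σ.

    Cell autofluorescence contributes ``autofluor_photons_per_um × length``
    photons per frame, spread uniformly over each cell's interior pixels.
    Emitters outside the field of view are clipped with a logged warning.
    """
    if psf_sigma_um <= 0:
        raise ValueError("psf_sigma_um must be positive")
    camera = camera or CameraModel()
    emitter_sets = emitters if isinstance(emitters, list) else [emitters]
    if cells is None:
        cells = [e.cell for e in emitter_sets if e.cell is not None]
    elif isinstance(cells, CellModel):
        cells = [cells]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    all_pos = np.vstack([e.positions_um for e in emitter_sets])
    photon_rates = np.concatenate(
        [np.full(e.n_emitters, e.photon_rate) for e in emitter_sets]
    )
    px = camera.pixel_size_um
    if shape is None:
        margin = 0.5  # µm beyond the outermost cell outline / emitter
        xs, ys = [all_pos[:, 0]], [all_pos[:, 1]]
        for cell in cells:
            half = cell.length_um / 2 + 0.2
            xs.append(np.array([cell.center_um[0] - half, cell.center_um[0] + half]))
            ys.append(np.array([cell.center_um[1] - half, cell.center_um[1] + half]))
        xmax = max(float(np.max(np.concatenate(xs))), 0.0) + margin
        ymax = max(float(np.max(np.concatenate(ys))), 0.0) + margin
        shape = (int(math.ceil(ymax / px)), int(math.ceil(xmax / px)))

    n_frames = states.n_frames if states is not None else 1
    if states is not None and states.states.shape[1] != all_pos.shape[0]:
        raise ValueError("states and emitters disagree on emitter count")

    patches = []
    n_clipped = 0
    for pos, rate in zip(all_pos, photon_rates):
        patch = _psf_patch(pos, rate, psf_sigma_um, px, shape)
        in_fov = 0 <= pos[0] <= shape[1] * px and 0 <= pos[1] <= shape[0] * px
        if patch is None or not in_fov:
            n_clipped += 1
        patches.append(patch)
    if n_clipped:
        logger.warning("%d emitter(s) outside the field of view were clipped", n_clipped)

    background = np.zeros(shape)
    for cell in cells:
        rows, cols = np.indices(shape)
        centers = np.column_stack(
            [(cols.ravel() + 0.5) * px, (rows.ravel() + 0.5) * px]
        )
        inside = cell.boundary_distance(centers).reshape(shape) <= 0
        npix = int(inside.sum())
        if npix and autofluor_photons_per_um > 0:
            background[inside] += autofluor_photons_per_um * cell.length_um / npix

    counts = np.empty((n_frames,) + shape)
    for t in range(n_frames):
        photons = background.copy()
        for i, patch in enumerate(patches):
            if patch is None:
                continue
            if states is None or states.states[t, i]:
                rs, cs, img = patch
                photons[rs, cs] += img
        if shot_noise:
            photons = rng.poisson(photons).astype(float)
        frame = camera.offset + photons / camera.gain
        if camera.read_noise_sd > 0:
            frame = frame + rng.normal(0.0, camera.read_noise_sd, size=shape)
        counts[t] = np.clip(frame, 0.0, None)

    meta = {
        "psf_sigma_um": psf_sigma_um,
        "autofluor_photons_per_um": autofluor_photons_per_um,
        "n_emitters": int(all_pos.shape[0]),
        "photon_rate": [float(e.photon_rate) for e in emitter_sets],
    }
    return ImageStack(
        counts=counts,
        pixel_size_um=px,
        frame_interval_s=frame_interval_s,
        camera=camera,
        metadata=meta,
    )


def simulate_tracks(
    n_tracks: int,
    d_um2_s: float,
    dt_s: float,
    n_steps: int,
    loc_sigma_um: float = 0.0,
    seed: int | np.random.Generator | None = None,
    field_um: float = 5.0,
    region: str = "noncentral",
) -> TrackSet:
    """Simulate 2-D Brownian trajectories with Gaussian localization error.

    Each track has ``n_steps`` time points at interval ``dt_s``; per-axis
    displacements are Normal(0, 2 D dt) and reported positions carry
    independent Normal(0, loc_sigma²) error per axis.  Track origins are
    uniform in a ``field_um`` × ``field_um`` box.  The ground-truth D is
    stored on the returned :class:`TrackSet`.
    """
    if d_um2_s < 0:
        raise ValueError("D must be nonnegative")
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tracks = []
    for i in range(n_tracks):
        origin = rng.uniform(0.0, field_um, size=2)
        steps = rng.normal(0.0, math.sqrt(2 * d_um2_s * dt_s), size=(n_steps - 1, 2))
        true = origin + np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        observed = true + rng.normal(0.0, loc_sigma_um, size=true.shape)
        tracks.append(
            Track(
                frames=np.arange(n_steps),
                positions_um=observed,
                region=region,
                track_id=i,
                true_positions_um=true,
            )
        )
    return TrackSet(
        tracks=tracks, dt_s=dt_s, true_d_um2_s=d_um2_s, loc_sigma_um=loc_sigma_um
    )


def simulate_confined_tracks(
    n_tracks: int,
    d_um2_s: float,
    dt_s: float,
    n_steps: int,
    radius_um: float,
    loc_sigma_um: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> TrackSet:
    """Brownian motion confined to a reflecting disc of given radius.

    Used to reproduce the MSD plateau expected for molecules tethered within
    a diffraction-limited region (e.g. at the divisome)."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tracks = []
    for i in range(n_tracks):
        # uniform start inside the disc
        while True:
            p = rng.uniform(-radius_um, radius_um, size=2)
            if np.hypot(*p) <= radius_um:
                break
        true = np.empty((n_steps, 2))
        true[0] = p
        for t in range(1, n_steps):
            q = true[t - 1] + rng.normal(0.0, math.sqrt(2 * d_um2_s * dt_s), size=2)
            rnorm = np.hypot(*q)
            while rnorm > radius_um:  # reflect radial overshoot
                q *= (2 * radius_um - rnorm) / rnorm
                rnorm = np.hypot(*q)
            true[t] = q
        observed = true + rng.normal(0.0, loc_sigma_um, size=true.shape)
        tracks.append(
            Track(
                frames=np.arange(n_steps),
                positions_um=observed,
                region="midcell",
                track_id=i,
                true_positions_um=true,
            )
        )
    return TrackSet(
        tracks=tracks, dt_s=dt_s, true_d_um2_s=d_um2_s, loc_sigma_um=loc_sigma_um
    )


def simulate_midcell_stoichiometries(
    n_spots: int = 150,
    units_range: tuple[int, int] = (1, 7),
    oligomer_size: int = 6,
    noise_sigma: float = 0.8,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spot-level ground truth for periodicity analysis, bypassing rendering.

    Each spot holds ``k`` copies of the oligomeric unit (``k`` uniform over
    ``units_range``), i.e. ``k × oligomer_size`` molecules, measured with
    additive Gaussian error of ``noise_sigma`` molecules (clipped at zero).

    Returns ``(true_molecule_counts, measured_values)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = units_range
    k = rng.integers(lo, hi + 1, size=n_spots)
    counts = (k * oligomer_size).astype(int)
    measured = np.clip(counts + rng.normal(0.0, noise_sigma, size=n_spots), 0.0, None)
    return counts, measured


@dataclass
class SimulationConfig:
    """Complete parameterization of one synthetic experiment.

    The same seed always produces bit-identical output.  Defaults mirror the
    acquisition regime the analysis targets: cells of 2–4.5 µm carrying ~40
    membrane monomers and one midcell cluster of 1–7 hexameric units, imaged
    at 80 nm pixels on an sCMOS camera.
    """

    seed: int = 0
    n_cells: int = 60
    n_monomers: int = 20
    cluster_units_range: tuple[int, int] = (1, 7)
    oligomer_size: int = 6
    photon_rate: float = 400.0
    psf_sigma_um: float = 0.12
    frame_interval_s: float = 0.0175
    n_frames: int = 1
    bleach_rate: float = 0.0
    cell_length_range_um: tuple[float, float] = (2.0, 4.5)
    cell_width_um: float = 1.0
    autofluor_photons_per_um: float = 200.0
    camera: CameraModel = field(default_factory=CameraModel)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        cam = d.pop("camera", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if cam is not None:
            cfg.camera = CameraModel(**cam)
        for key in ("cluster_units_range", "cell_length_range_um"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["cluster_units_range"] = list(self.cluster_units_range)
        d["cell_length_range_um"] = list(self.cell_length_range_um)
        return d
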