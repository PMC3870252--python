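"""End-to-end orchestration: simulate → quantify → periodicity / diffusion.

A :class:`RunConfig` (YAML-serializable) fully determines a run; every run
writes a ``manifest.json`` (config + package version + seed) from which all
outputs can be reproduced bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bleaching import binomial_thin
from .containers import CameraModel
from .diffusion import ensemble_msd, estimate_D
from .io import read_image_stack, read_roi_table, write_json, write_tracks
from .periodicity import (
    DEFAULT_BANDWIDTH,
    DEFAULT_SEARCH_RANGE,
    analyze_periodicity,
    to_stoichiometry,
)
from .quantify import (
    UnitIntensity,
    calibrate_unit_intensity,
    estimate_background,
    fit_elliptical_gaussian,
    is_single_step,
)
from .synthetic import (
    EmitterSet,
    build_cell_model,
    render_stack,
    sample_emitters,
    simulate_bleaching,
    simulate_midcell_stoichiometries,
    simulate_tracks,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_stoichiometry_pipeline", "run_diffusion_pipeline"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run (see the YAML schema in the docs).

    ``stoichiometry`` and ``diffusion`` are parameter blocks for the two
    pipelines; either may be omitted.  A single integer ``seed`` drives all
    randomness.
    """

    seed: int = 0
    stoichiometry: dict = field(default_factory=dict)
    diffusion: dict = field(default_factory=dict)
    camera: CameraModel = field(default_factory=CameraModel)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cam = d.get("camera")
        return cls(
            seed=int(d.get("seed", 0)),
            stoichiometry=dict(d.get("stoichiometry", {})),
            diffusion=dict(d.get("diffusion", {})),
            camera=CameraModel(**cam) if cam else CameraModel(),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stoichiometry": self.stoichiometry,
            "diffusion": self.diffusion,
            "camera": {
                "offset": self.camera.offset,
                "gain": self.camera.gain,
                "read_noise_sd": self.camera.read_noise_sd,
                "pixel_size_um": self.camera.pixel_size_um,
            },
        }


def _write_manifest(config: RunConfig, outdir: Path) -> None:
    write_json(
        outdir / "manifest.json",
        {"config": config.to_dict(), "package_version": __version__,
         "seed": config.seed},
    )


def _calibrate_from_simulation(
    rng: np.random.Generator,
    camera: CameraModel,
    n_cal: int = 100,
    photon_rate: float = 400.0,
    psf_sigma_um: float = 0.12,
    bleach_rate: float = 0.08,
    n_frames: int = 25,
) -> UnitIntensity:
    """Simulate single-fluorophore reference spots (the LacY-YPet standard),
    keep those whose trace disappears in a single step, and calibrate."""
    shape = (21, 21)
    npix = shape[0] * shape[1]
    centre_um = (
        (shape[1] / 2) * camera.pixel_size_um,
        (shape[0] / 2) * camera.pixel_size_um,
    )
    intensities = []
    for _ in range(n_cal):
        emitters = EmitterSet(
            positions_um=np.array([centre_um]),
            cluster_id=np.array([0]),
            photon_rate=photon_rate,
        )
        states = simulate_bleaching(1, bleach_rate, n_frames, rng)
        stack = render_stack(
            emitters, states, cells=[], psf_sigma_um=psf_sigma_um,
            camera=camera, shape=shape, seed=rng,
        )
        trace = stack.counts.sum(axis=(1, 2)) - camera.offset * npix
        if not is_single_step(trace):
            continue
        fit = fit_elliptical_gaussian(
            stack.counts[0], (shape[0] // 2, shape[1] // 2), window=9,
            background=camera.offset,
            fixed_sigma=psf_sigma_um / camera.pixel_size_um,
        )
        if fit.converged and not fit.no_spot:
            intensities.append(fit.integrated_intensity)
    return calibrate_unit_intensity(intensities)


def _measure_simulated_cells(
    rng: np.random.Generator, block: dict, camera: CameraModel
) -> pd.DataFrame:
    """Render one midcell cluster per simulated cell and fit it."""
    n_cells = int(block.get("n_cells", 60))
    n_monomers = int(block.get("n_monomers", 20))
    photon_rate = float(block.get("photon_rate", 400.0))
    psf_sigma = float(block.get("psf_sigma_um", 0.12))
    oligomer_size = int(block.get("oligomer_size", 6))
    autofluor = float(block.get("autofluor_photons_per_um", 200.0))
    length_range = tuple(block.get("cell_length_range_um", (2.0, 4.5)))
    width = float(block.get("cell_width_um", 1.0))
    px = camera.pixel_size_um

    records = []
    for i in range(n_cells):
        length = float(rng.uniform(*length_range))
        cls = "constricted" if rng.random() < 0.5 else "unconstricted"
        cell = build_cell_model(
            length, width, cls, center_um=(0.5 + length / 2, 0.5 + width / 2)
        )
        emitters = sample_emitters(
            cell, n_monomers, 1, oligomer_size=oligomer_size,
            photon_rate=photon_rate, seed=rng,
        )
        shape = (
            int(np.ceil((width + 1.0) / px)),
            int(np.ceil((length + 1.0) / px)),
        )
        stack = render_stack(
            emitters, None, cells=cell, psf_sigma_um=psf_sigma, camera=camera,
            shape=shape, autofluor_photons_per_um=autofluor, seed=rng,
        )
        frame = stack.counts[0]
        cluster_pos = emitters.positions_um[emitters.cluster_id == 1][0]
        seed_rc = (
            int(np.clip(round(cluster_pos[1] / px - 0.5), 4, shape[0] - 5)),
            int(np.clip(round(cluster_pos[0] / px - 0.5), 4, shape[1] - 5)),
        )
        from .quantify import CellROI

        roi = CellROI(0, 0, shape[0], shape[1], cell_length_um=length,
                      constriction_class=cls)
        window = (seed_rc[0] - 4, seed_rc[1] - 4, seed_rc[0] + 5, seed_rc[1] + 5)
        background = estimate_background(frame, roi, exclusion=window)
        fit = fit_elliptical_gaussian(frame, seed_rc, window=9, background=background)
        true_units = emitters.cluster_units()[1]
        records.append(
            {
                "cell": i,
                "cell_length_um": length,
                "constriction_class": cls,
                "intensity": fit.integrated_intensity,
                "converged": fit.converged,
                "no_spot": fit.no_spot,
                "true_units": true_units,
                "true_molecules": true_units * oligomer_size,
            }
        )
        if not fit.converged or fit.no_spot:
            logger.warning("cell %d: midcell fit flagged (converged=%s, no_spot=%s)",
                           i, fit.converged, fit.no_spot)
    return pd.DataFrame(records)


def run_stoichiometry_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Full midcell stoichiometry workflow, simulated or from input files.

    Modes (``stoichiometry.mode``):

    - ``direct`` (default): generate spot stoichiometries straight from the
      oligomer ground-truth model (no rendering) and run the periodicity
      analysis.
    - ``images``: render synthetic cells, fit midcell spots, calibrate the
      single-fluorophore unit from simulated reference spots, convert to
      stoichiometries, then run the periodicity analysis.
    - with ``stack``/``rois`` paths: analyse user-supplied data (requires
      ``unit_intensity`` or a ``calibration_csv`` of single-molecule spot
      intensities).

    Writes stoichiometries.csv, spectrum.csv, summary.json and manifest.json
    into ``outdir``; returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_manifest(config, outdir)
    block = config.stoichiometry
    rng = np.random.default_rng(config.seed)
    bandwidth = float(block.get("bandwidth", DEFAULT_BANDWIDTH))
    search_range = tuple(block.get("search_range", DEFAULT_SEARCH_RANGE))
    summary: dict = {"seed": config.seed}

    if "stack" in block or "rois" in block:
        stack = read_image_stack(block["stack"])
        rois = read_roi_table(block["rois"])
        if "unit_intensity" in block:
            unit = UnitIntensity(float(block["unit_intensity"]),
                                 float(block.get("unit_se", 0.0)), 0)
        elif "calibration_csv" in block:
            cal = pd.read_csv(block["calibration_csv"])
            unit = calibrate_unit_intensity(cal["intensity"].to_numpy())
        else:
            raise ValueError("input mode needs unit_intensity or calibration_csv")
        records = []
        for i, roi in enumerate(rois):
            frame = stack.counts[0]
            if roi.midcell_rc is not None:
                seed_rc = (int(roi.midcell_rc[0]), int(roi.midcell_rc[1]))
            else:
                sub = frame[roi.row0 : roi.row1, roi.col0 : roi.col1]
                r, c = np.unravel_index(int(np.argmax(sub)), sub.shape)
                seed_rc = (roi.row0 + int(r), roi.col0 + int(c))
            window = (seed_rc[0] - 4, seed_rc[1] - 4, seed_rc[0] + 5, seed_rc[1] + 5)
            background = estimate_background(frame, roi, exclusion=window)
            fit = fit_elliptical_gaussian(frame, seed_rc, window=9,
                                          background=background)
            records.append(
                {"cell": i, "cell_length_um": roi.cell_length_um,
                 "constriction_class": roi.constriction_class,
                 "intensity": fit.integrated_intensity,
                 "converged": fit.converged, "no_spot": fit.no_spot}
            )
        spots = pd.DataFrame(records)
        good = spots[spots["converged"] & ~spots["no_spot"]]
        values = to_stoichiometry(good["intensity"].to_numpy(), unit)
        values = np.clip(values, 0.0, None)
        spots.to_csv(outdir / "spots.csv", index=False)
        summary["unit_intensity"] = {"mean": unit.mean, "se": unit.se,
                                     "n_spots": unit.n_spots}
    elif block.get("mode", "direct") == "images":
        unit = _calibrate_from_simulation(
            rng, config.camera,
            n_cal=int(block.get("n_calibration_spots", 100)),
            photon_rate=float(block.get("photon_rate", 400.0)),
            psf_sigma_um=float(block.get("psf_sigma_um", 0.12)),
        )
        spots = _measure_simulated_cells(rng, block, config.camera)
        good = spots[spots["converged"] & ~spots["no_spot"]]
        values = to_stoichiometry(good["intensity"].to_numpy(), unit)
        values = np.clip(values, 0.0, None)
        spots.to_csv(outdir / "spots.csv", index=False)
        summary["unit_intensity"] = {"mean": unit.mean, "se": unit.se,
                                     "n_spots": unit.n_spots}
    else:
        counts, values = simulate_midcell_stoichiometries(
            n_spots=int(block.get("n_spots", 150)),
            units_range=tuple(block.get("cluster_units_range", (1, 7))),
            oligomer_size=int(block.get("oligomer_size", 6)),
            noise_sigma=float(block.get("noise_sigma", 0.8)),
            seed=rng,
        )
        summary["true_mean_molecules"] = float(np.mean(counts))

    pd.DataFrame({"stoichiometry": values}).to_csv(
        outdir / "stoichiometries.csv", index=False
    )
    result = analyze_periodicity(values, bandwidth=bandwidth,
                                 search_range=search_range)
    pd.DataFrame(
        {"periodicity": result.periodicity_grid, "power": result.power}
    ).to_csv(outdir / "spectrum.csv", index=False)
    summary.update(
        {
            "n_spots": int(np.asarray(values).size),
            "peak_periodicity": result.peak_periodicity,
            "peak_hwhm": result.peak_hwhm,
            "bandwidth": bandwidth,
            "search_range": list(search_range),
        }
    )

    thinning_p = block.get("thinning_p")
    if thinning_p is not None:
        thinned = binomial_thin(values, float(thinning_p), seed=rng)
        thinned_result = analyze_periodicity(
            thinned.astype(float), bandwidth=bandwidth, search_range=search_range
        )
        pd.DataFrame({"stoichiometry": thinned}).to_csv(
            outdir / "stoichiometries_thinned.csv", index=False
        )
        summary["thinning"] = {
            "survive_p": float(thinning_p),
            "peak_periodicity": thinned_result.peak_periodicity,
            "peak_hwhm": thinned_result.peak_hwhm,
        }

    write_json(outdir / "summary.json", summary)
    logger.info("stoichiometry pipeline: peak %s molecules over %d spots",
                summary["peak_periodicity"], summary["n_spots"])
    return summary


def run_diffusion_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Tracking → MSD → diffusion-coefficient workflow.

    With a simulation block, generates a mobile "noncentral" population and an
    immobile "midcell" population and estimates D for each; with
    ``tracks_csv`` (requires ``dt_s``) analyses supplied trajectories.
    Writes tracks CSV, msd.csv and summary.json into ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_manifest(config, outdir)
    block = config.diffusion
    rng = np.random.default_rng(config.seed + 1)
    n_points = int(block.get("n_points_fit", 4))
    max_lag = int(block.get("max_lag", 10))

    tracksets: dict[str, object] = {}
    if "tracks_csv" in block:
        if "dt_s" not in block:
            raise ValueError("dt_s (frame interval) is required with tracks_csv")
        from .io import read_tracks

        tracksets["input"] = read_tracks(block["tracks_csv"], float(block["dt_s"]))
    else:
        dt = float(block.get("dt_s", 0.01))
        n_tracks = int(block.get("n_tracks", 30))
        n_steps = int(block.get("n_steps", 100))
        loc = float(block.get("loc_sigma_um", 0.02))
        tracksets["noncentral"] = simulate_tracks(
            n_tracks, float(block.get("d_um2_s", 0.039)), dt, n_steps,
            loc_sigma_um=loc, seed=rng,
        )
        tracksets["midcell"] = simulate_tracks(
            n_tracks, 0.0, dt, n_steps, loc_sigma_um=loc, seed=rng,
            region="midcell",
        )

    summary: dict = {"seed": config.seed, "regions": {}}
    msd_tables = []
    for region, ts in tracksets.items():
        msd = ensemble_msd(ts, max_lag=max_lag)
        est = estimate_D(msd, n_points=n_points)
        msd_tables.append(
            pd.DataFrame(
                {"region": region, "lag_s": msd.lag_times_s,
                 "msd_um2": msd.msd_um2, "n_pairs": msd.n_pairs}
            )
        )
        write_tracks(outdir / f"tracks_{region}.csv", ts)
        summary["regions"][region] = {
            "d_um2_s": est.d_um2_s,
            "se_d": est.se_d,
            "intercept_um2": est.intercept_um2,
            "near_immobile": est.near_immobile,
            "n_tracks": len(ts),
            "true_d_um2_s": getattr(ts, "true_d_um2_s", None),
        }
        logger.info("diffusion pipeline [%s]: D = %.3g µm²/s (near_immobile=%s)",
                    region, est.d_um2_s, est.near_immobile)
    pd.concat(msd_tables, ignore_index=True).to_csv(outdir / "msd.csv", index=False)
    write_json(outdir / "summary.json", summary)
    return summary
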