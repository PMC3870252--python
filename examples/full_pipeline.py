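"""The end-to-end pipelines: simulate → quantify → periodicity + diffusion.

Runs the image-based stoichiometry pipeline (render cells, calibrate the
single-fluorophore unit from simulated reference spots, fit midcell spots,
convert to molecule counts, detect periodicity) and the diffusion pipeline,
writing CSV/JSON outputs plus a reproducibility manifest to ./pipeline_demo.
"""

from oligospot import RunConfig, run_diffusion_pipeline, \
    run_stoichiometry_pipeline

config = RunConfig(
    seed=4,
    stoichiometry={"mode": "images", "n_cells": 50, "n_calibration_spots": 60,
                   "n_monomers": 10},
    diffusion={"d_um2_s": 0.039, "n_tracks": 30, "n_steps": 100,
               "loc_sigma_um": 0.02},
)

stoich = run_stoichiometry_pipeline(config, "pipeline_demo/stoichiometry")
print(f"unit intensity: {stoich['unit_intensity']['mean']:.1f} ± "
      f"{stoich['unit_intensity']['se']:.1f} counts "
      f"({stoich['unit_intensity']['n_spots']} validated single fluorophores)")
print(f"midcell spots:  {stoich['n_spots']}")
print(f"periodicity:    {stoich['peak_periodicity']:.2f} molecules "
      f"(HWHM {stoich['peak_hwhm']:.2f})")

diff = run_diffusion_pipeline(config, "pipeline_demo/diffusion")
for region, res in diff["regions"].items():
    print(f"{region:11s} D = {res['d_um2_s']:.4f} µm²/s "
          f"(near_immobile={res['near_immobile']})")
print()
print("Outputs (spots.csv, stoichiometries.csv, spectrum.csv, tracks CSVs,")
print("msd.csv, summary.json, manifest.json) are under ./pipeline_demo;")
print("re-running with the same manifest reproduces them bit-for-bit.")
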