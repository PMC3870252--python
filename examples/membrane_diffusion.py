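"""Membrane diffusion from single-particle tracks via MSD analysis.

Simulates 30 Brownian tracks at the membrane-protein rate 0.039 µm²/s and 30
immobile midcell emitters, both observed with 20 nm localization noise at
10 ms frames, and recovers D from the slope of the first four MSD points.
"""

from oligospot import ensemble_msd, estimate_D, simulate_confined_tracks, \
    simulate_tracks

mobile = simulate_tracks(30, 0.039, 0.01, 100, loc_sigma_um=0.02, seed=5)
immobile = simulate_tracks(30, 0.0, 0.01, 100, loc_sigma_um=0.02, seed=6)

est_mobile = estimate_D(ensemble_msd(mobile, max_lag=10), n_points=4)
est_immobile = estimate_D(ensemble_msd(immobile, max_lag=10), n_points=4)

print(f"mobile:    D = {est_mobile.d_um2_s:.4f} µm²/s "
      f"(truth 0.039, intercept {est_mobile.intercept_um2 * 1e3:.2f}e-3 µm²)")
print(f"immobile:  D = {est_immobile.d_um2_s:.2e} µm²/s, "
      f"near_immobile = {est_immobile.near_immobile}")

confined = simulate_confined_tracks(40, 0.039, 0.01, 100, radius_um=0.15, seed=7)
msd = ensemble_msd(confined, max_lag=30)
print(f"confined:  MSD plateaus at {msd.msd_um2[-1]:.4f} µm² "
      f"(free motion would reach {4 * 0.039 * msd.lag_times_s[-1]:.3f} µm²)")
print()
print("D = slope/4 of the initial MSD; the free intercept absorbs the")
print("4·sigma_loc² localization-error offset.  Confinement makes the MSD")
print("approach a horizontal asymptote instead of growing linearly.")
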