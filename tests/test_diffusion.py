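"""Spot detection, track linking, MSD and diffusion-coefficient estimation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from oligospot import (
    EmitterSet,
    MSDCurve,
    TrackSet,
    detect_per_frame,
    ensemble_msd,
    estimate_D,
    link_nearest_neighbour,
    render_stack,
    simulate_confined_tracks,
    simulate_tracks,
)
from oligospot.containers import Track


def brute_force_msd(tracks: TrackSet, max_lag: int):
    """All-pairs MSD oracle by explicit enumeration (tiny tracks only)."""
    sums = {m: 0.0 for m in range(1, max_lag + 1)}
    counts = {m: 0 for m in range(1, max_lag + 1)}
    for track in tracks:
        for i, j in itertools.combinations(range(len(track)), 2):
            lag = int(track.frames[j] - track.frames[i])
            if 1 <= lag <= max_lag:
                d = track.positions_um[j] - track.positions_um[i]
                sums[lag] += float(d @ d)
                counts[lag] += 1
    lags = [m for m in sums if counts[m] > 0]
    return (
        np.array(lags, dtype=float) * tracks.dt_s,
        np.array([sums[m] / counts[m] for m in lags]),
        np.array([counts[m] for m in lags]),
    )


class TestDetection:
    def test_single_emitter_detected_subpixel(self, quiet_camera):
        em = EmitterSet(positions_um=np.array([[1.0, 0.9]]),
                        cluster_id=np.array([0]), photon_rate=2000.0)
        stack = render_stack(em, None, cells=[], camera=quiet_camera,
                            shape=(25, 25), seed=0)
        det = detect_per_frame(stack, threshold_sd=5)
        assert len(det) == 1
        px = quiet_camera.pixel_size_um
        assert abs(det.iloc[0]["x_um"] - 1.0) < 0.5 * px
        assert abs(det.iloc[0]["y_um"] - 0.9) < 0.5 * px

    def test_blank_frames_mostly_empty(self, camera):
        """At 5 sigma, false positives on blank frames are rare."""
        em = EmitterSet(positions_um=np.empty((0, 2)), cluster_id=np.empty(0, int))
        n_det = 0
        for seed in range(20):
            stack = render_stack(em, None, cells=[], camera=camera,
                                shape=(30, 30), seed=seed)
            n_det += len(detect_per_frame(stack, threshold_sd=5))
        assert n_det <= 1

    def test_two_separated_emitters(self, quiet_camera):
        px = quiet_camera.pixel_size_um
        pos = np.array([[8 * px, 10 * px], [18 * px, 10 * px]])  # 10 px apart
        em = EmitterSet(positions_um=pos, cluster_id=np.zeros(2, int),
                        photon_rate=2000.0)
        stack = render_stack(em, None, cells=[], camera=quiet_camera,
                            shape=(25, 25), seed=1)
        assert len(detect_per_frame(stack, threshold_sd=5)) == 2


def detections_from_tracks(tracks: TrackSet) -> pd.DataFrame:
    rows = []
    for track in tracks:
        for f, (x, y) in zip(track.frames, track.positions_um):
            rows.append({"frame": int(f), "x_um": x, "y_um": y,
                         "true_id": track.track_id})
    return pd.DataFrame(rows)


class TestLinking:
    def test_two_stationary_spots_two_tracks(self):
        rows = []
        for f in range(10):
            rows.append({"frame": f, "x_um": 1.0, "y_um": 1.0})
            rows.append({"frame": f, "x_um": 4.0, "y_um": 4.0})
        ts = link_nearest_neighbour(pd.DataFrame(rows), max_disp_um=0.5)
        assert len(ts) == 2
        assert all(len(t) == 10 for t in ts)

    def test_large_jump_splits_track(self):
        rows = [
            {"frame": 0, "x_um": 1.0, "y_um": 1.0},
            {"frame": 1, "x_um": 1.01, "y_um": 1.0},
            {"frame": 2, "x_um": 3.0, "y_um": 3.0},  # jump >> max_disp
        ]
        ts = link_nearest_neighbour(pd.DataFrame(rows), max_disp_um=0.2)
        lengths = sorted(len(t) for t in ts)
        assert lengths == [1, 2]

    def test_gap_closing(self):
        rows = [{"frame": f, "x_um": 1.0, "y_um": 1.0} for f in (0, 1, 3, 4)]
        ts = link_nearest_neighbour(pd.DataFrame(rows), max_disp_um=0.5, max_gap=1)
        assert len(ts) == 1 and len(ts.tracks[0]) == 4
        ts = link_nearest_neighbour(pd.DataFrame(rows), max_disp_um=0.5, max_gap=0)
        assert len(ts) == 2

    def test_linking_accuracy_on_brownian_ground_truth(self):
        """>= 95% of consecutive links match the simulator's ground truth."""
        D, dt = 0.039, 0.01
        sim = simulate_tracks(20, D, dt, 50, loc_sigma_um=0.02, seed=5,
                              field_um=12.0)
        det = detections_from_tracks(sim)
        max_disp = 3 * math.sqrt(4 * D * dt)
        linked = link_nearest_neighbour(det, max_disp_um=max_disp, dt_s=dt)
        # map every linked consecutive pair back to true ids via positions
        key = {(int(r.frame), round(r.x_um, 9), round(r.y_um, 9)): r.true_id
               for r in det.itertuples()}
        good = bad = 0
        for track in linked:
            for i in range(len(track) - 1):
                a = key[(int(track.frames[i]), round(track.positions_um[i][0], 9),
                         round(track.positions_um[i][1], 9))]
                b = key[(int(track.frames[i + 1]),
                         round(track.positions_um[i + 1][0], 9),
                         round(track.positions_um[i + 1][1], 9))]
                good += a == b
                bad += a != b
        assert good / (good + bad) >= 0.95


class TestMSD:
    def test_stationary_tracks_zero_msd(self):
        tracks = [Track(frames=np.arange(10), positions_um=np.ones((10, 2)))]
        msd = ensemble_msd(TrackSet(tracks=tracks, dt_s=0.01), max_lag=5)
        assert np.allclose(msd.msd_um2, 0.0)

    def test_ballistic_motion_quadratic(self):
        """Straight-line motion at speed v gives MSD(tau) = (v tau)^2."""
        v, dt = 2.0, 0.1
        t = np.arange(20)
        pos = np.column_stack([v * dt * t, np.zeros(20)])
        msd = ensemble_msd(
            TrackSet(tracks=[Track(frames=t, positions_um=pos)], dt_s=dt),
            max_lag=6,
        )
        np.testing.assert_allclose(msd.msd_um2, (v * msd.lag_times_s) ** 2)

    def test_matches_brute_force_on_tiny_tracks(self):
        """Exact agreement with the all-pairs enumeration oracle."""
        rng = np.random.default_rng(3)
        tracks = []
        for i in range(4):
            n = int(rng.integers(2, 6))
            frames = np.sort(rng.choice(np.arange(8), size=n, replace=False))
            tracks.append(Track(frames=frames,
                                positions_um=rng.normal(size=(n, 2))))
        ts = TrackSet(tracks=tracks, dt_s=0.05)
        msd = ensemble_msd(ts, max_lag=5)
        lag_o, msd_o, n_o = brute_force_msd(ts, max_lag=5)
        np.testing.assert_allclose(msd.lag_times_s, lag_o)
        np.testing.assert_allclose(msd.msd_um2, msd_o, rtol=1e-12)
        np.testing.assert_array_equal(msd.n_pairs, n_o)

    def test_brownian_msd_matches_closed_form(self):
        """MSD(tau) within 3 MC SE of 4 D tau + 4 sigma^2 for first 4 lags."""
        D, dt, loc = 0.039, 0.01, 0.02
        reps = []
        for seed in range(20):
            ts = simulate_tracks(30, D, dt, 100, loc_sigma_um=loc, seed=seed)
            reps.append(ensemble_msd(ts, max_lag=4).msd_um2)
        reps = np.asarray(reps)
        expected = 4 * D * (dt * np.arange(1, 5)) + 4 * loc**2
        se = reps.std(axis=0, ddof=1) / np.sqrt(reps.shape[0])
        assert np.all(np.abs(reps.mean(axis=0) - expected) <= 3 * se)

    def test_no_usable_tracks_raises(self):
        tracks = [Track(frames=np.array([0]), positions_um=np.zeros((1, 2)))]
        with pytest.raises(ValueError):
            ensemble_msd(TrackSet(tracks=tracks, dt_s=0.01))


class TestEstimateD:
    def test_exact_linear_msd(self):
        tau = 0.01 * np.arange(1, 7)
        msd = MSDCurve(lag_times_s=tau, msd_um2=4 * 0.05 * tau,
                       n_pairs=np.full(6, 100))
        est = estimate_D(msd)
        assert est.d_um2_s == pytest.approx(0.05)
        assert est.intercept_um2 == pytest.approx(0.0, abs=1e-12)

    def test_intercept_absorbs_offset(self):
        tau = 0.01 * np.arange(1, 7)
        msd = MSDCurve(lag_times_s=tau, msd_um2=4 * 0.05 * tau + 0.01,
                       n_pairs=np.full(6, 100))
        est = estimate_D(msd)
        assert est.d_um2_s == pytest.approx(0.05)
        assert est.intercept_um2 == pytest.approx(0.01)

    def test_too_few_lags(self):
        msd = MSDCurve(lag_times_s=np.array([0.01]), msd_um2=np.array([0.001]),
                       n_pairs=np.array([5]))
        with pytest.raises(ValueError):
            estimate_D(msd, n_points=4)

    @pytest.mark.parametrize("d_true", [0.005, 0.039, 0.061])
    def test_recovery_within_15_percent(self, d_true):
        """Mean D over replicates of 30 tracks x 100 steps within 15%."""
        ests = []
        for seed in range(10):
            ts = simulate_tracks(30, d_true, 0.01, 100, loc_sigma_um=0.02,
                                 seed=seed)
            ests.append(estimate_D(ensemble_msd(ts, max_lag=10)).d_um2_s)
        assert np.mean(ests) == pytest.approx(d_true, rel=0.15)

    def test_immobile_emitters_flagged(self):
        """Static emitters with 20 nm localization noise read as immobile."""
        ests = []
        for seed in range(10):
            ts = simulate_tracks(30, 0.0, 0.01, 100, loc_sigma_um=0.02,
                                 seed=seed)
            est = estimate_D(ensemble_msd(ts, max_lag=10))
            ests.append(est.d_um2_s)
            assert est.near_immobile
        assert abs(np.mean(ests)) < 4e-4

    def test_confined_tracks_plateau(self):
        """Reflecting-disc confinement bends the MSD below the free line."""
        D, dt, radius = 0.039, 0.01, 0.15
        ts = simulate_confined_tracks(40, D, dt, 100, radius_um=radius, seed=2)
        msd = ensemble_msd(ts, max_lag=30)
        tau_max = msd.lag_times_s[-1]
        assert msd.msd_um2[-1] < 4 * D * tau_max / 2
        # plateau near the confinement value r^2 (disc: E = r^2)
        assert msd.msd_um2[-1] < 1.5 * radius**2
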