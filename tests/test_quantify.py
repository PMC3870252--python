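"""Background estimation, Gaussian spot fitting, calibration, cell counting."""

import math

import numpy as np
import pytest

from oligospot import (
    CameraModel,
    CellROI,
    EmitterSet,
    build_cell_model,
    calibrate_unit_intensity,
    estimate_background,
    fit_autofluorescence,
    fit_elliptical_gaussian,
    is_single_step,
    render_stack,
    sample_emitters,
    whole_cell_intensity,
)
from oligospot.quantify import _gaussian2d


def render_gaussian(shape, x0, y0, sx, sy, theta, amp, offset):
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    return _gaussian2d((xs.astype(float), ys.astype(float)),
                       x0, y0, sx, sy, theta, amp, offset)


class TestBackground:
    def test_constant_image(self):
        image = np.full((20, 20), 100.0)
        roi = CellROI(0, 0, 20, 20, cell_length_um=3.0)
        assert estimate_background(image, roi) == 100.0

    def test_exclusion_removes_spot(self):
        image = np.full((20, 20), 100.0)
        image[8:13, 8:13] = 5000.0
        roi = CellROI(0, 0, 20, 20, cell_length_um=3.0)
        assert estimate_background(image, roi, exclusion=(8, 8, 13, 13)) == 100.0

    def test_empty_after_exclusion(self):
        image = np.full((10, 10), 1.0)
        roi = CellROI(2, 2, 5, 5, cell_length_um=3.0)
        with pytest.raises(ValueError):
            estimate_background(image, roi, exclusion=(0, 0, 10, 10))

    def test_recovers_simulated_background(self, cell, quiet_camera):
        em = EmitterSet(positions_um=np.empty((0, 2)), cluster_id=np.empty(0, int))
        stack = render_stack(em, None, cells=cell, camera=quiet_camera,
                            autofluor_photons_per_um=200.0, seed=0)
        shape = stack.frame_shape
        roi = CellROI(0, 0, shape[0], shape[1], cell_length_um=cell.length_um)
        est = estimate_background(stack.counts[0], roi)
        # most pixels are outside the cell, so the median sits near the offset
        assert abs(est - quiet_camera.offset) < 2.0


class TestGaussianFit:
    def test_noiseless_roundtrip(self):
        """Parameters of a rendered elliptical Gaussian are recovered to 1e-3."""
        truth = dict(x0=10.3, y0=9.6, sx=1.8, sy=1.5, theta=0.6, amp=500.0,
                     offset=20.0)
        image = render_gaussian((21, 21), **{k: v for k, v in zip(
            ("x0", "y0", "sx", "sy", "theta", "amp", "offset"), truth.values())})
        fit = fit_elliptical_gaussian(image, (10, 10), window=15, background=20.0)
        assert fit.converged and not fit.no_spot
        assert fit.center[0] == pytest.approx(truth["x0"], abs=1e-3)
        assert fit.center[1] == pytest.approx(truth["y0"], abs=1e-3)
        assert fit.sigma_major == pytest.approx(1.8, rel=1e-3)
        assert fit.sigma_minor == pytest.approx(1.5, rel=1e-3)
        assert fit.orientation == pytest.approx(0.6, abs=1e-3)
        assert fit.amplitude == pytest.approx(500.0, rel=1e-3)
        assert fit.integrated_intensity == pytest.approx(
            500.0 * 2 * math.pi * 1.8 * 1.5, rel=1e-3
        )

    def test_integrated_intensity_identity(self):
        """integrated = amplitude x 2 pi sigma_major sigma_minor, always."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            image = render_gaussian(
                (15, 15), 7 + rng.uniform(-1, 1), 7 + rng.uniform(-1, 1),
                rng.uniform(1.2, 2.5), rng.uniform(0.8, 1.2),
                rng.uniform(0, 3), rng.uniform(50, 800), 10.0,
            ) + rng.normal(0, 2, (15, 15))
            fit = fit_elliptical_gaussian(image, (7, 7), window=13)
            assert fit.integrated_intensity == pytest.approx(
                fit.amplitude * 2 * math.pi * fit.sigma_major * fit.sigma_minor
            )
            assert fit.sigma_major >= fit.sigma_minor > 0
            assert 0 <= fit.orientation < math.pi

    def test_flat_image_is_no_spot(self):
        fit = fit_elliptical_gaussian(np.full((11, 11), 100.0), (5, 5), window=9)
        assert fit.no_spot

    def test_axis_aligned_mode(self):
        image = render_gaussian((15, 15), 7.0, 7.0, 2.0, 1.4, 0.0, 300.0, 5.0)
        fit = fit_elliptical_gaussian(image, (7, 7), window=13, rotated=False)
        assert fit.orientation in (0.0, pytest.approx(math.pi / 2))
        assert fit.sigma_major == pytest.approx(2.0, rel=1e-3)

    def test_window_outside_image_raises(self):
        with pytest.raises(ValueError):
            fit_elliptical_gaussian(np.zeros((10, 10)), (1, 1), window=9)

    def test_simulated_spot_intensity_within_poisson_error(self, quiet_camera):
        """Fitted integrated intensity within 3 SD of ground truth photons/gain."""
        photons = 2400.0  # one hexamer at 400 photons per fluorophore
        em = EmitterSet(positions_um=np.array([[1.0, 1.0]]),
                        cluster_id=np.array([0]), photon_rate=photons)
        errs = []
        for seed in range(10):
            stack = render_stack(em, None, cells=[], camera=quiet_camera,
                                shape=(25, 25), seed=seed)
            rc = (round(1.0 / 0.08 - 0.5), round(1.0 / 0.08 - 0.5))
            fit = fit_elliptical_gaussian(stack.counts[0], rc, window=11,
                                          background=quiet_camera.offset)
            errs.append(fit.integrated_intensity - photons / quiet_camera.gain)
        sd = math.sqrt(photons) / quiet_camera.gain
        assert abs(np.mean(errs)) <= 3 * sd / math.sqrt(len(errs))


class TestSingleStepDetector:
    def test_clean_single_step(self, rng):
        trace = np.r_[np.full(20, 200.0), np.full(20, 0.0)] + rng.normal(0, 5, 40)
        assert is_single_step(trace)

    def test_two_steps_rejected(self, rng):
        trace = np.r_[np.full(15, 400.0), np.full(15, 200.0), np.full(15, 0.0)]
        assert not is_single_step(trace + rng.normal(0, 5, 45))

    def test_constant_trace_rejected(self, rng):
        assert not is_single_step(np.full(30, 100.0) + rng.normal(0, 5, 30))

    def test_upward_step_rejected(self, rng):
        trace = np.r_[np.full(20, 0.0), np.full(20, 200.0)] + rng.normal(0, 5, 40)
        assert not is_single_step(trace)


class TestUnitIntensity:
    def test_single_value(self):
        unit = calibrate_unit_intensity([25.0])
        assert unit.mean == 25.0 and unit.se == 0.0 and unit.n_spots == 1

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            calibrate_unit_intensity([])

    def test_high_cv_warns(self):
        with pytest.warns(UserWarning, match="coefficient of variation"):
            calibrate_unit_intensity([1.0, 100.0, 1.0, 100.0])

    def test_unbiased_on_simulated_single_emitters(self, quiet_camera):
        """Mean unit intensity within 3 SE of photon_rate / gain."""
        photons = 50.0
        em = EmitterSet(positions_um=np.array([[1.0, 1.0]]),
                        cluster_id=np.array([0]), photon_rate=photons)
        intensities = []
        for seed in range(200):
            stack = render_stack(em, None, cells=[], camera=quiet_camera,
                                shape=(25, 25), seed=seed)
            rc = (round(1.0 / 0.08 - 0.5), round(1.0 / 0.08 - 0.5))
            fit = fit_elliptical_gaussian(stack.counts[0], rc, window=11,
                                          background=quiet_camera.offset,
                                          fixed_sigma=0.12 / 0.08)
            if fit.converged and not fit.no_spot:
                intensities.append(fit.integrated_intensity)
        unit = calibrate_unit_intensity(intensities)
        assert abs(unit.mean - photons / quiet_camera.gain) <= 3 * unit.se


class TestAutofluorescence:
    def test_exact_line(self):
        lengths = np.array([2.0, 3.0, 4.0, 5.0])
        model = fit_autofluorescence(lengths, 10 * lengths + 5)
        assert model.slope == pytest.approx(10.0)
        assert model.intercept == pytest.approx(5.0)

    def test_degenerate_lengths_raise(self):
        with pytest.raises(ValueError):
            fit_autofluorescence([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])

    def test_recovers_simulated_slope(self, quiet_camera, rng):
        """OLS slope within 3 SE of the generator's photons-per-micron truth."""
        autofluor = 300.0
        lengths, totals = [], []
        for i in range(25):
            length = float(rng.uniform(2.0, 5.0))
            cell = build_cell_model(length, 1.0,
                                    center_um=(0.5 + length / 2, 1.0))
            em = EmitterSet(positions_um=np.empty((0, 2)),
                            cluster_id=np.empty(0, int))
            stack = render_stack(em, None, cells=cell, camera=quiet_camera,
                                autofluor_photons_per_um=autofluor, seed=rng)
            shape = stack.frame_shape
            roi = CellROI(0, 0, shape[0], shape[1], cell_length_um=length)
            totals.append(whole_cell_intensity(stack, roi, None, quiet_camera))
            lengths.append(length)
        model = fit_autofluorescence(lengths, totals)
        assert abs(model.slope - autofluor / quiet_camera.gain) <= 3 * model.slope_se


class TestWholeCellIntensity:
    def test_offset_only_is_zero(self, quiet_camera):
        image = np.full((20, 30), quiet_camera.offset)
        roi = CellROI(2, 2, 18, 28, cell_length_um=3.0)
        assert whole_cell_intensity(image, roi, None, quiet_camera) == 0.0

    def test_empty_cell_near_zero(self, cell, quiet_camera, rng):
        em = EmitterSet(positions_um=np.empty((0, 2)), cluster_id=np.empty(0, int))
        autofluor = 200.0
        stack = render_stack(em, None, cells=cell, camera=quiet_camera,
                            autofluor_photons_per_um=autofluor, seed=rng)
        shape = stack.frame_shape
        roi = CellROI(0, 0, shape[0], shape[1], cell_length_um=cell.length_um)
        from oligospot.quantify import AutofluorescenceModel

        model = AutofluorescenceModel(slope=autofluor / quiet_camera.gain,
                                      intercept=0.0)
        corrected = whole_cell_intensity(stack, roi, model, quiet_camera)
        total_photons = autofluor * cell.length_um
        noise_sd = np.sqrt(total_photons) / quiet_camera.gain
        assert abs(corrected) <= 4 * noise_sd

    def test_counts_69_monomers_within_10_percent(self, quiet_camera):
        """Corrected whole-cell intensity / unit recovers the emitter number."""
        photons = 400.0
        n_true = 69
        recovered = []
        for seed in range(5):
            cell = build_cell_model(3.5, 1.0, center_um=(2.25, 1.0))
            em = sample_emitters(cell, n_true, 0, photon_rate=photons, seed=seed)
            stack = render_stack(em, None, cells=cell, camera=quiet_camera,
                                autofluor_photons_per_um=200.0, seed=seed + 100)
            shape = stack.frame_shape
            roi = CellROI(0, 0, shape[0], shape[1], cell_length_um=3.5)
            from oligospot.quantify import AutofluorescenceModel

            model = AutofluorescenceModel(slope=200.0 / quiet_camera.gain,
                                          intercept=0.0)
            corrected = whole_cell_intensity(stack, roi, model, quiet_camera)
            recovered.append(corrected / (photons / quiet_camera.gain))
        assert np.mean(recovered) == pytest.approx(n_true, rel=0.10)

    def test_linearity_in_emitter_number(self, quiet_camera):
        """Whole-cell signal is linear in emitter count, slope = photons/gain."""
        from scipy import stats

        photons = 400.0
        ns, signals = [], []
        for seed, n in enumerate([30, 60, 90, 120]):
            cell = build_cell_model(4.0, 1.0, center_um=(2.5, 1.0))
            em = sample_emitters(cell, n, 0, photon_rate=photons, seed=seed)
            stack = render_stack(em, None, cells=cell, camera=quiet_camera,
                                seed=seed + 50)
            shape = stack.frame_shape
            roi = CellROI(0, 0, shape[0], shape[1], cell_length_um=4.0)
            signals.append(whole_cell_intensity(stack, roi, None, quiet_camera))
            ns.append(n)
        fit = stats.linregress(ns, signals)
        assert fit.slope == pytest.approx(photons / quiet_camera.gain, rel=0.05)
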