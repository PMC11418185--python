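import math

import numpy as np
import pytest

from waspeye import (FWHM_FACTOR, GroundTruthRF, KernelFit, RasterScan,
                     ScreenGeometry, StimulusSpec, acceptance_angle,
                     build_rf_map, convolve_kernel_with_target,
                     estimate_rf_centre, fit_kernel, gen_bar_sweep_set,
                     gen_raster_scan, gen_raster_traces, pixel_to_degree,
                     render_target)
from conftest import grid_moments


# ---------------------------------------------------------------------------
# pixel -> degree
# ---------------------------------------------------------------------------

class TestPixelToDegree:
    # 1 mm per pixel makes the expected angles easy to state
    geom = ScreenGeometry(px_width=500, px_height=500, width_mm=500.0,
                          height_mm=500.0, distance_mm=200.0)

    def test_centre_maps_to_origin(self):
        loc = pixel_to_degree((0.0, 0.0), self.geom)
        assert (loc.longitude, loc.latitude) == (0.0, 0.0)

    def test_equal_offset_and_distance_gives_45_deg(self):
        loc = pixel_to_degree((200.0, 0.0), self.geom)
        assert loc.longitude == pytest.approx(45.0, abs=1e-12)

    def test_tangent_correction(self):
        # arctan(34.9/200) = 9.90 deg: smaller than the linear scaling
        loc = pixel_to_degree((0.0, 34.9), self.geom)
        assert loc.latitude == pytest.approx(9.90, abs=5e-3)

    def test_offset_beyond_screen_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            pixel_to_degree((400.0, 0.0), self.geom)


# ---------------------------------------------------------------------------
# target rendering
# ---------------------------------------------------------------------------

class TestRenderTarget:
    offs = StimulusSpec().offsets()  # 61 cells, 0.1 deg spacing

    def test_single_cell_target(self):
        img = render_target(0.1, self.offs, self.offs)
        assert img.max() == pytest.approx(1.0)
        assert np.count_nonzero(img) == 1

    def test_two_degree_square_area(self):
        img = render_target(2.0, self.offs, self.offs)
        cell_area = 0.1 * 0.1
        assert img.sum() * cell_area == pytest.approx(4.00, rel=1e-12)
        # interior is fully covered
        assert np.count_nonzero(img == 1.0) >= 19 * 19

    @pytest.mark.parametrize("shift", [0.0, 0.013, 0.05, 0.0721])
    def test_integral_invariant_under_subcell_shift(self, shift):
        base = render_target(1.5, self.offs, self.offs).sum()
        moved = render_target(1.5, self.offs, self.offs,
                              centre=(shift, -shift)).sum()
        assert moved == pytest.approx(base, rel=1e-12)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError, match="target_size"):
            render_target(0.0, self.offs)


# ---------------------------------------------------------------------------
# kernel (*) target model
# ---------------------------------------------------------------------------

class TestConvolution:
    offs = StimulusSpec().offsets()

    def test_near_delta_kernel_reproduces_target(self):
        target = render_target(2.0, self.offs, self.offs)
        model = convolve_kernel_with_target((0.0, 0.0, 0.01, 0.01, 2.5),
                                            target, self.offs, self.offs)
        assert np.allclose(model, 2.5 * target, atol=1e-6)

    def test_near_delta_target_reproduces_kernel(self):
        """With a one-cell target the model samples the kernel at x0, y0."""
        target = np.zeros((61, 61))
        target[30, 30] = 1.0
        x0, y0, sh, sv, amp = 0.5, -0.3, 0.45, 0.6, 2.0
        model = convolve_kernel_with_target((x0, y0, sh, sv, amp), target,
                                            self.offs, self.offs)
        gh = np.exp(-0.5 * ((self.offs - x0) / sh) ** 2)
        gv = np.exp(-0.5 * ((self.offs - y0) / sv) ** 2)
        gh, gv = gh / gh.sum(), gv / gv.sum()
        assert np.allclose(model, amp * np.outer(gv, gh), atol=1e-12)

    def test_variance_additivity(self):
        """Discrete convolution adds the second moments of its factors."""
        target = render_target(1.5, self.offs, self.offs)
        model = convolve_kernel_with_target((0.0, 0.0, 0.55, 0.55, 1.0),
                                            target, self.offs, self.offs)
        _, var_model = grid_moments(model, self.offs, axis=0)
        _, var_target = grid_moments(target, self.offs, axis=0)
        assert var_model == pytest.approx(0.55 ** 2 + var_target, rel=2e-3)

    def test_nonpositive_sigma_rejected(self):
        target = render_target(1.5, self.offs, self.offs)
        with pytest.raises(ValueError, match="sigma"):
            convolve_kernel_with_target((0, 0, -0.5, 0.5, 1.0), target,
                                        self.offs, self.offs)


# ---------------------------------------------------------------------------
# RF centre from bar sweeps
# ---------------------------------------------------------------------------

class TestCentreEstimation:
    def test_noiseless_zero_latency_recovery(self):
        rf = GroundTruthRF(centre_x=3.2, centre_y=-1.1, latency=0.0)
        est = estimate_rf_centre(gen_bar_sweep_set(rf))
        # one sample interval = bar_speed / rate = 0.2 deg
        assert est.x == pytest.approx(3.2, abs=0.2)
        assert est.y == pytest.approx(-1.1, abs=0.2)

    def test_latency_bias_and_cancellation(self):
        rf = GroundTruthRF(centre_x=0.0, centre_y=0.0, latency=0.02)
        est = estimate_rf_centre(gen_bar_sweep_set(rf))
        # each single-direction estimate is displaced by velocity x latency
        assert est.per_direction["right"] == pytest.approx(1.92, abs=0.02)
        assert est.per_direction["left"] == pytest.approx(-1.92, abs=0.02)
        # the opposing-sweep midpoint cancels the latency
        assert est.x == pytest.approx(0.0, abs=0.02)
        assert est.y == pytest.approx(0.0, abs=0.02)

    def test_time_order_invariance(self):
        rf = GroundTruthRF(centre_x=1.0, centre_y=0.5, latency=0.0)
        sweeps = gen_bar_sweep_set(rf)
        ref = estimate_rf_centre(sweeps)
        for tr in sweeps.traces.values():
            tr.time = tr.time[::-1]
            tr.voltage = tr.voltage[::-1]
        rev = estimate_rf_centre(sweeps)
        assert (rev.x, rev.y) == (ref.x, ref.y)

    def test_missing_direction_flags_axis(self):
        rf = GroundTruthRF(latency=0.0)
        sweeps = gen_bar_sweep_set(rf)
        del sweeps.traces["left"]
        est = estimate_rf_centre(sweeps)
        assert est.x is None and est.y is not None and not est.complete

    def test_flat_trace_error_names_direction(self):
        rf = GroundTruthRF(latency=0.0)
        sweeps = gen_bar_sweep_set(rf)
        sweeps.traces["up"].voltage = np.zeros_like(
            sweeps.traces["up"].voltage)
        with pytest.raises(ValueError, match="up"):
            estimate_rf_centre(sweeps)


# ---------------------------------------------------------------------------
# trace gridding
# ---------------------------------------------------------------------------

class TestBuildRFMap:
    @pytest.mark.parametrize("direction", ["lr", "tb"])
    def test_noiseless_round_trip_is_exact(self, direction):
        rf = GroundTruthRF(sigma_h=0.6, sigma_v=0.45, latency=0.01)
        grid = gen_raster_scan(rf, direction=direction)
        rebuilt = build_rf_map(gen_raster_traces(rf, direction=direction))
        assert np.array_equal(grid.response, rebuilt.response)

    def test_repeat_averaging_idempotent(self):
        rf = GroundTruthRF(latency=0.0)
        one = build_rf_map(gen_raster_traces(rf, n_repeats=1))
        two = build_rf_map(gen_raster_traces(rf, n_repeats=2))
        assert np.allclose(one.response, two.response)
        assert two.n_repeats == 2

    def test_constant_trace_gives_zero_map(self):
        rf = GroundTruthRF(latency=0.0)
        traces = gen_raster_traces(rf)
        traces.data["voltage_mV"] = 2.5  # resting potential, no response
        grid = build_rf_map(traces)
        assert np.allclose(grid.response, 0.0)

    def test_inconsistent_line_length_names_line(self):
        rf = GroundTruthRF(latency=0.0)
        traces = gen_raster_traces(rf)
        df = traces.data
        drop = df[(df.line_index == 5)].index[:3]
        traces.data = df.drop(drop)
        with pytest.raises(ValueError, match="line 5"):
            build_rf_map(traces)


# ---------------------------------------------------------------------------
# kernel fitting
# ---------------------------------------------------------------------------

class TestFitKernel:
    def test_noiseless_recovery(self, quiet_rf):
        scan = gen_raster_scan(quiet_rf)
        fit = fit_kernel(scan)
        assert fit.converged
        assert fit.sigma_v == pytest.approx(0.55, rel=1e-2)
        assert fit.sigma_h == pytest.approx(0.55, rel=1e-2)
        assert fit.x0 == pytest.approx(scan.ground_truth.x0, abs=0.01)

    def test_amplitude_linearity(self, quiet_rf):
        scan = gen_raster_scan(quiet_rf)
        fit1 = fit_kernel(scan)
        scan2 = RasterScan(response=2.0 * scan.response,
                           x_offsets=scan.x_offsets,
                           y_offsets=scan.y_offsets, stim=scan.stim)
        fit2 = fit_kernel(scan2)
        assert fit2.sigma_v == pytest.approx(fit1.sigma_v, rel=1e-3)
        assert fit2.sigma_h == pytest.approx(fit1.sigma_h, rel=1e-3)
        assert fit2.x0 == pytest.approx(fit1.x0, abs=1e-3)
        assert fit2.amplitude == pytest.approx(2 * fit1.amplitude, rel=1e-3)

    def test_deconvolution_narrows(self, quiet_rf):
        """Fitted kernel FWHM < FWHM of the raw (target-blurred) map."""
        scan = gen_raster_scan(quiet_rf)
        fit = fit_kernel(scan)
        profile = scan.response.sum(axis=1)
        half = profile.max() / 2
        raw_fwhm = (profile >= half).sum() * scan.stim.spacing
        assert fit.delta_rho_v < raw_fwhm

    def test_flat_raster_rejected(self, stim):
        flat = RasterScan(response=np.zeros((61, 61)),
                          x_offsets=stim.offsets(),
                          y_offsets=stim.offsets(), stim=stim)
        with pytest.raises(ValueError, match="flat"):
            fit_kernel(flat)

    def test_isotropic_mode_shares_sigma(self, quiet_rf):
        fit = fit_kernel(gen_raster_scan(quiet_rf), isotropic=True)
        assert fit.sigma_h == fit.sigma_v


# ---------------------------------------------------------------------------
# acceptance angle
# ---------------------------------------------------------------------------

class TestAcceptanceAngle:
    @pytest.mark.parametrize("sigma, expected", [(0.5, 1.1774), (1.0, 2.3548)])
    def test_fwhm_closed_form(self, sigma, expected):
        fit = KernelFit(x0=0, y0=0, sigma_h=sigma, sigma_v=sigma,
                        amplitude=1.0, sse=0.0, converged=True)
        assert acceptance_angle(fit) == pytest.approx(expected, abs=5e-5)
        assert fit.delta_rho_v == FWHM_FACTOR * fit.sigma_v

    def test_unconverged_fit_warns(self):
        fit = KernelFit(x0=0, y0=0, sigma_h=0.5, sigma_v=0.5, amplitude=1.0,
                        sse=1.0, converged=False)
        with pytest.warns(UserWarning, match="converge"):
            acceptance_angle(fit)

    def test_frontal_cell_recovery_with_noise(self):
        """Noisy frontal-scale cells (true delta_rho 1.18 deg) recover the
        acceptance angle to within 5% on average."""
        values = []
        for seed in range(10):
            rf = GroundTruthRF.from_acceptance_angles(
                1.18, 1.18, amplitude=3.0, latency=0.0,
                noise_sd=0.05 * 3.0, seed=seed)
            stim = StimulusSpec(target_size=1.5)
            fit = fit_kernel(gen_raster_scan(rf, stim))
            values.append(acceptance_angle(fit))
        assert np.mean(values) == pytest.approx(1.18, rel=0.05)
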