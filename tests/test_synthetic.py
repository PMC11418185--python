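import math

import numpy as np
import pytest

from waspeye import (DensityField, GroundTruthRF, StimulusSpec,
                     gen_bar_sweep_set, gen_facet_observations,
                     gen_raster_scan, gen_raster_traces)
from conftest import grid_moments


# ---------------------------------------------------------------------------
# stimulus validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs, match", [
    (dict(target_contrast=0.5), "contrast"),
    (dict(target_contrast=-1.5), "contrast"),
    (dict(n_lines=1), "n_lines"),
    (dict(target_size=7.0), "roi_size"),
    (dict(bar_speed=0.0), "bar_speed"),
    (dict(sample_rate=-10.0), "sample_rate"),
])
def test_stimulus_invariants(kwargs, match):
    with pytest.raises(ValueError, match=match):
        StimulusSpec(**kwargs)


def test_default_raster_geometry():
    stim = StimulusSpec()
    assert stim.spacing == pytest.approx(0.1)
    assert stim.rate == pytest.approx(480.0)
    offs = stim.offsets()
    assert offs.size == 61 and offs[0] == -3.0 and offs[-1] == 3.0


def test_amplitude_linearity_ceiling():
    with pytest.raises(ValueError, match="linearity"):
        GroundTruthRF(amplitude=5.4)


# ---------------------------------------------------------------------------
# raster scans
# ---------------------------------------------------------------------------

class TestRasterScan:
    def test_point_target_reproduces_kernel(self):
        """Convolution with a (near-)delta target is the kernel itself."""
        rf = GroundTruthRF(sigma_h=0.5, sigma_v=0.7, latency=0.0)
        stim = StimulusSpec(target_size=0.1)  # single raster cell
        scan = gen_raster_scan(rf, stim)
        offs = stim.offsets()
        gh = np.exp(-0.5 * (offs / 0.5) ** 2)
        gv = np.exp(-0.5 * (offs / 0.7) ** 2)
        expected = np.outer(gv, gh)
        expected *= scan.response.max() / expected.max()
        assert np.allclose(scan.response, expected, atol=1e-9)
        iy, ix = np.unravel_index(np.argmax(scan.response),
                                  scan.response.shape)
        assert offs[ix] == 0.0 and offs[iy] == 0.0

    def test_vertical_moment_additivity(self, quiet_rf):
        """Second moments of kernel and rendered target add under convolution."""
        from waspeye import render_target
        scan = gen_raster_scan(quiet_rf)  # sigma_v = 0.55, target 2.0
        offs = scan.y_offsets
        target = render_target(scan.stim.target_size, offs, offs)
        _, var_scan = grid_moments(scan.response, offs, axis=0)
        _, var_target = grid_moments(target, offs, axis=0)
        assert var_scan == pytest.approx(0.55 ** 2 + var_target, rel=2e-3)

    def test_same_seed_bit_identical(self):
        rf = GroundTruthRF(noise_sd=0.2, seed=42)
        a = gen_raster_scan(rf)
        b = gen_raster_scan(rf)
        assert np.array_equal(a.response, b.response)
        c = gen_raster_scan(GroundTruthRF(noise_sd=0.2, seed=43))
        assert not np.array_equal(a.response, c.response)

    def test_direct_convolution_oracle(self):
        """Noise-free scans match an independent brute-force convolution."""
        rf = GroundTruthRF(centre_x=0.3, centre_y=-0.2, sigma_h=0.5,
                           sigma_v=0.6, latency=0.0)
        stim = StimulusSpec(n_lines=31, line_spacing=0.2, target_size=1.5)
        scan = gen_raster_scan(rf, stim, roi_centre=(0.0, 0.0))
        offs = stim.offsets()
        # brute force: m[j,i] = A * sum_kl T[k,l] Gy[j-k+c] Gx[i-l+c], with
        # unit-mass sampled-Gaussian taps and zero outside the tap range
        from waspeye import render_target
        target = render_target(1.5, offs, offs)
        gx = np.exp(-0.5 * ((offs - 0.3) / 0.5) ** 2)
        gy = np.exp(-0.5 * ((offs + 0.2) / 0.6) ** 2)
        gx, gy = gx / gx.sum(), gy / gy.sum()
        n, c = offs.size, (offs.size - 1) // 2
        tap = lambda g, idx: g[idx] if 0 <= idx < n else 0.0
        brute = np.zeros_like(scan.response)
        for j in range(n):
            for i in range(n):
                brute[j, i] = 3.0 * sum(
                    target[k, l] * tap(gy, j - k + c) * tap(gx, i - l + c)
                    for k in range(n) for l in range(n) if target[k, l])
        assert np.allclose(scan.response, brute, atol=1e-12)

    def test_rf_outside_roi_rejected(self):
        rf = GroundTruthRF(centre_x=5.0, latency=0.0)
        with pytest.raises(ValueError, match="outside the ROI"):
            gen_raster_scan(rf, roi_centre=(0.0, 0.0))

    def test_latency_shifts_apparent_centre(self):
        rf = GroundTruthRF(latency=0.02)
        scan = gen_raster_scan(rf)
        assert scan.ground_truth.x0 == pytest.approx(48 * 0.02)


# ---------------------------------------------------------------------------
# bar sweeps
# ---------------------------------------------------------------------------

class TestBarSweeps:
    def test_extremum_at_centre_zero_latency(self):
        rf = GroundTruthRF(centre_x=3.2, centre_y=-1.1, latency=0.0)
        sweeps = gen_bar_sweep_set(rf)
        stim = sweeps.stim
        for name, centre in [("right", 3.2), ("left", 3.2),
                             ("up", -1.1), ("down", -1.1)]:
            tr = sweeps.traces[name]
            t_star = tr.time[np.argmin(tr.voltage)]
            pos = tr.start + tr.velocity * (t_star - stim.pre_stimulus)
            assert pos == pytest.approx(centre, abs=stim.bar_speed / stim.rate)

    def test_latency_displaces_extremum(self):
        rf = GroundTruthRF(centre_x=0.0, centre_y=0.0, latency=0.02)
        sweeps = gen_bar_sweep_set(rf)
        stim = sweeps.stim
        pos = {}
        for name in ("left", "right"):
            tr = sweeps.traces[name]
            t_star = tr.time[np.argmin(tr.voltage)]
            pos[name] = tr.start + tr.velocity * (t_star - stim.pre_stimulus)
        assert pos["right"] == pytest.approx(1.92, abs=0.21)
        assert pos["left"] == pytest.approx(-1.92, abs=0.21)

    def test_opposing_sweeps_mirror_for_central_rf(self):
        rf = GroundTruthRF(centre_x=0.0, centre_y=0.0, latency=0.0)
        sweeps = gen_bar_sweep_set(rf)
        up, down = sweeps.traces["up"], sweeps.traces["down"]
        assert np.allclose(up.voltage, down.voltage[:], atol=1e-12)
        # and each trace is symmetric in time about its extremum
        v = up.voltage
        i = int(np.argmin(v))
        k = min(i, v.size - 1 - i)
        assert np.allclose(v[i - k:i], v[i + k:i:-1], atol=1e-9)

    def test_determinism(self):
        rf = GroundTruthRF(noise_sd=0.3, seed=5)
        a = gen_bar_sweep_set(rf).traces["left"].voltage
        b = gen_bar_sweep_set(rf).traces["left"].voltage
        assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# facet lattices
# ---------------------------------------------------------------------------

class TestFacetLattices:
    def test_constant_field_analytic_density(self):
        field = DensityField.constant(1.0)
        assert field.density(0.0, 0.0) == pytest.approx(2 / math.sqrt(3))
        assert field.density(40.0, -30.0) == pytest.approx(1.1547, abs=1e-4)

    def test_inverse_square_density_scaling(self):
        one = DensityField.constant(1.0).density(10.0, 10.0)
        two = DensityField.constant(2.0).density(10.0, 10.0)
        assert two == pytest.approx(one / 4.0, rel=1e-12)

    def test_observations_deterministic_and_integer(self):
        field = DensityField.constant(1.5)
        obs1 = gen_facet_observations(field)
        obs2 = gen_facet_observations(field)
        assert [(o.facet_x, o.facet_y) for o in obs1] == \
               [(o.facet_x, o.facet_y) for o in obs2]
        assert all(isinstance(o.facet_x, int) for o in obs1)

    def test_directions_outside_boundary_omitted(self, caplog):
        field = DensityField.constant(1.0)
        with caplog.at_level("INFO", logger="waspeye.synthetic"):
            obs = gen_facet_observations(
                field, boundary=((-20.0, 20.0), (-20.0, 20.0)),
                directions=[(0.0, 0.0), (50.0, 0.0)])
        assert len(obs) == 1
        assert "omitted" in caplog.text

    def test_acute_zone_minimum_location(self):
        field = DensityField.acute_zone()
        lon = np.arange(-100, 101, 5.0)
        lat = np.arange(-80, 81, 5.0)
        vals = field.delta_phi(lon[None, :], lat[:, None])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        assert abs(lon[j] - 15.0) <= 5.0 and abs(lat[i] + 15.0) <= 5.0
        assert vals.min() == pytest.approx(1.0, abs=0.01)
        # rises to ~3 deg toward the dorsal pole
        assert field.delta_phi(15.0, 90.0) == pytest.approx(3.0, rel=0.01)
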