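"""Synthetic recordings and facet lattices with known ground truth.

Every quantity the analysis estimates is generated here from explicit
parameters so recovery can be checked exactly:

* bar sweeps and raster scans of a photoreceptor whose angular
  sensitivity is an elliptical Gaussian -- the cell *hyperpolarizes* to a
  dark target, so generated voltages are negative-going, with additive
  i.i.d. Gaussian recording noise and a fixed response latency;
* spherical facet lattices built from a smooth coordinate map whose
  analytic local density equals 2/(sqrt(3)*delta_phi^2) facets per square
  degree, rounded to the integer facet the pseudopupil would actually
  single out.

All generators are deterministic given the seed carried by the ground
truth object.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import ndtr

from .eye_mapping import FacetObservation, lambert_v
from .receptive_field import (BarSweepSet, RasterScan, RasterTraces,
                              SweepTrace, convolve_kernel_with_target,
                              render_target, FWHM_FACTOR)
from .stimulus import StimulusSpec

__all__ = [
    "GroundTruthRF",
    "DensityField",
    "gen_raster_scan",
    "gen_raster_traces",
    "gen_bar_sweep_set",
    "gen_facet_observations",
]

logger = logging.getLogger(__name__)

#: Linearity ceiling for synthetic response amplitudes (mV): small-signal
#: Gaussian-kernel fitting assumes responses stay in the linear range.
MAX_AMPLITUDE_MV = 5.0


@dataclass(frozen=True)
class GroundTruthRF:
    """True receptive-field parameters behind a synthetic recording.

    ``centre_x, centre_y`` are screen coordinates in degrees; ``sigma_h,
    sigma_v`` the Gaussian angular-sensitivity SDs in degrees;
    ``amplitude`` the peak hyperpolarization magnitude in mV (reported
    positive); ``latency`` the response delay in seconds; ``noise_sd``
    the additive recording-noise SD in mV.
    """

    centre_x: float = 0.0
    centre_y: float = 0.0
    sigma_h: float = 0.55
    sigma_v: float = 0.55
    amplitude: float = 3.0
    latency: float = 0.02
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_h <= 0 or self.sigma_v <= 0:
            raise ValueError("sigma_h and sigma_v must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.amplitude > MAX_AMPLITUDE_MV:
            raise ValueError(
                f"amplitude {self.amplitude} mV exceeds the {MAX_AMPLITUDE_MV}"
                f" mV linearity ceiling of the small-signal model")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.latency < 0:
            raise ValueError("latency must be non-negative")

    @classmethod
    def from_acceptance_angles(cls, delta_rho_h: float, delta_rho_v: float,
                               **kwargs) -> "GroundTruthRF":
        """Construct from FWHM acceptance angles instead of Gaussian SDs."""
        return cls(sigma_h=delta_rho_h / FWHM_FACTOR,
                   sigma_v=delta_rho_v / FWHM_FACTOR, **kwargs)

    @property
    def delta_rho_h(self) -> float:
        return FWHM_FACTOR * self.sigma_h

    @property
    def delta_rho_v(self) -> float:
        return FWHM_FACTOR * self.sigma_v


@dataclass
class RasterGroundTruth:
    """Ground truth attached to a synthetic raster, in ROI coordinates.

    ``x0, y0`` are the *apparent* kernel centre: the true centre shifted
    along the drift axis by drift_speed x latency, which is where any
    latency-blind analysis of the map will (correctly) locate the peak.
    """

    rf: GroundTruthRF
    x0: float
    y0: float
    sigma_h: float
    sigma_v: float
    amplitude: float


# ---------------------------------------------------------------------------
# Raster scans
# ---------------------------------------------------------------------------

def _noiseless_grid(rf: GroundTruthRF, stim: StimulusSpec,
                    roi_centre: tuple[float, float],
                    direction: str) -> tuple[np.ndarray, RasterGroundTruth]:
    """Noise-free hyperpolarization-magnitude grid and its ground truth."""
    offs = stim.offsets()
    rel_x = rf.centre_x - roi_centre[0]
    rel_y = rf.centre_y - roi_centre[1]
    half = stim.roi_size / 2.0
    if abs(rel_x) > half or abs(rel_y) > half:
        raise ValueError(
            f"RF centre ({rf.centre_x}, {rf.centre_y}) lies outside the ROI "
            f"centred at {roi_centre}")
    shift = stim.drift_speed * rf.latency
    if direction == "lr":
        x0, y0 = rel_x + shift, rel_y
    elif direction == "tb":
        x0, y0 = rel_x, rel_y - shift
    else:
        raise ValueError(f"unknown drift direction {direction!r}")
    target = render_target(stim.target_size, offs, offs)
    grid = convolve_kernel_with_target(
        (x0, y0, rf.sigma_h, rf.sigma_v, rf.amplitude), target, offs, offs)
    truth = RasterGroundTruth(rf=rf, x0=x0, y0=y0, sigma_h=rf.sigma_h,
                              sigma_v=rf.sigma_v, amplitude=rf.amplitude)
    return grid, truth


def gen_raster_scan(rf: GroundTruthRF, stim: StimulusSpec = StimulusSpec(),
                    roi_centre: tuple[float, float] | None = None,
                    direction: str = "lr") -> RasterScan:
    """Synthesize a gridded raster-scan receptive-field map.

    The noise-free map is ``amplitude x (Gaussian kernel (*) rendered
    target)`` sampled on the raster grid (as a hyperpolarization
    magnitude; the underlying membrane voltage is its negative), plus
    additive Gaussian noise.  The ROI is centred on the RF unless
    ``roi_centre`` says otherwise, and the kernel appears shifted along
    the drift axis by drift_speed x latency exactly as in a real scan.
    """
    if roi_centre is None:
        roi_centre = (rf.centre_x, rf.centre_y)
    clean, truth = _noiseless_grid(rf, stim, roi_centre, direction)
    rng = np.random.default_rng(rf.seed)
    voltage = -clean + rng.normal(0.0, rf.noise_sd, clean.shape) \
        if rf.noise_sd > 0 else -clean
    offs = stim.offsets()
    return RasterScan(response=-voltage, x_offsets=offs, y_offsets=offs,
                      stim=stim, n_repeats=1, roi_centre=tuple(roi_centre),
                      ground_truth=truth)


def gen_raster_traces(rf: GroundTruthRF, stim: StimulusSpec = StimulusSpec(),
                      n_repeats: int = 1,
                      roi_centre: tuple[float, float] | None = None,
                      direction: str = "lr") -> RasterTraces:
    """Synthesize line-by-line raster voltage traces.

    Each raster line starts with a pre-stimulus baseline window, then one
    voltage sample per raster cell as the target drifts through the ROI;
    :func:`waspeye.receptive_field.build_rf_map` reconstructs exactly the
    grid of :func:`gen_raster_scan` from the noiseless version of these
    traces.
    """
    import pandas as pd

    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if roi_centre is None:
        roi_centre = (rf.centre_x, rf.centre_y)
    clean, truth = _noiseless_grid(rf, stim, roi_centre, direction)
    rng = np.random.default_rng(rf.seed)
    offs = stim.offsets()
    n = offs.size
    rate = stim.rate
    n_pre = int(round(stim.pre_stimulus * rate))
    pre_t = np.arange(n_pre) / rate
    stim_t = stim.pre_stimulus + (offs - offs[0]) / stim.drift_speed

    frames = []
    for rep in range(n_repeats):
        for line in range(n):
            if direction == "lr":
                values = clean[line, :]
            else:  # drift top->bottom through column `line`
                values = clean[::-1, line]
            v = np.concatenate([np.zeros(n_pre), -values])
            if rf.noise_sd > 0:
                v = v + rng.normal(0.0, rf.noise_sd, v.size)
            frames.append(pd.DataFrame({
                "time_s": np.concatenate([pre_t, stim_t]),
                "voltage_mV": v,
                "line_index": line,
                "repeat": rep,
                "direction": direction,
            }))
    data = pd.concat(frames, ignore_index=True)
    return RasterTraces(data=data, stim=stim, direction=direction,
                        roi_centre=tuple(roi_centre), ground_truth=truth)


# ---------------------------------------------------------------------------
# Bar sweeps
# ---------------------------------------------------------------------------

def _bar_profile(offset: np.ndarray, sigma: float, width: float) -> np.ndarray:
    """Fraction of a Gaussian RF dimmed by a long bar centred ``offset`` away."""
    a = (offset + width / 2.0) / sigma
    b = (offset - width / 2.0) / sigma
    return ndtr(a) - ndtr(b)


def gen_bar_sweep_set(rf: GroundTruthRF,
                      stim: StimulusSpec = StimulusSpec()) -> BarSweepSet:
    """Synthesize the four cardinal bar sweeps of one cell.

    Each trace shows a hyperpolarization whose extremum occurs when the
    bar centre crosses the RF centre, delayed by the response latency;
    'right'/'up' sweeps move toward positive screen x/y.
    """
    rng = np.random.default_rng(rf.seed)
    half = stim.sweep_span / 2.0
    duration = stim.pre_stimulus + stim.sweep_span / stim.bar_speed
    t = np.arange(0.0, duration, 1.0 / stim.rate)
    width = stim.bar_size[0]

    setup = {
        "right": (-half, stim.bar_speed, rf.centre_x, rf.sigma_h),
        "left": (half, -stim.bar_speed, rf.centre_x, rf.sigma_h),
        "up": (-half, stim.bar_speed, rf.centre_y, rf.sigma_v),
        "down": (half, -stim.bar_speed, rf.centre_y, rf.sigma_v),
    }
    traces = {}
    for name, (start, vel, centre, sigma) in setup.items():
        pos = start + vel * np.clip(t - stim.pre_stimulus, 0.0, None)
        # the response at time t reflects the bar position a latency ago
        v = -rf.amplitude * _bar_profile(pos - vel * rf.latency - centre,
                                         sigma, width)
        if rf.noise_sd > 0:
            v = v + rng.normal(0.0, rf.noise_sd, v.size)
        traces[name] = SweepTrace(direction=name, time=t, voltage=v,
                                  start=start, velocity=vel)
    return BarSweepSet(traces=traces, stim=stim, ground_truth=rf)


# ---------------------------------------------------------------------------
# Facet lattices
# ---------------------------------------------------------------------------

class DensityField:
    """Smooth interommatidial-angle field over the visual sphere.

    The field is separable in Lambert equal-area coordinates
    (u = longitude, v = (180/pi) sin latitude):

        delta_phi(lon, lat)^2 = p(u) * q(v)

    which lets the generator build an *exactly* consistent facet lattice:
    the planar map W(u, v) = (int du/p, int dv/q) passed through the
    inverse hexagonal-lattice basis has Jacobian determinant
    2/(sqrt(3) delta_phi^2) facets per true square degree everywhere.
    """

    def __init__(self, p, q, grid_spacing: float = 10.0):
        self.p = p
        self.q = q
        self.grid_spacing = float(grid_spacing)

    @classmethod
    def constant(cls, delta_phi: float,
                 grid_spacing: float = 10.0) -> "DensityField":
        if delta_phi <= 0:
            raise ValueError("delta_phi must be positive")
        return cls(p=lambda u: delta_phi ** 2, q=lambda v: 1.0,
                   grid_spacing=grid_spacing)

    @classmethod
    def acute_zone(cls, min_delta_phi: float = 1.0, min_lon: float = 15.0,
                   min_lat: float = -15.0, dorsal_delta_phi: float = 3.0,
                   lon_gradient: float = 0.3,
                   grid_spacing: float = 10.0) -> "DensityField":
        """Fronto-ventral acute zone rising smoothly toward the dorsal pole.

        delta_phi is smallest (``min_delta_phi``) at (min_lon, min_lat)
        and climbs quadratically to ``dorsal_delta_phi`` at the dorsal
        pole, with a gentler quadratic rise away from the acute zone in
        longitude -- the qualitative layout of a vespid worker eye.
        """
        v0 = float(lambert_v(min_lat))
        v_top = float(lambert_v(90.0))
        ratio = (dorsal_delta_phi / min_delta_phi) ** 2 - 1.0

        def p(u):
            return 1.0 + lon_gradient * ((u - min_lon) / 85.0) ** 2

        def q(v):
            return min_delta_phi ** 2 * (
                1.0 + ratio * ((v - v0) / (v_top - v0)) ** 2)

        return cls(p=p, q=q, grid_spacing=grid_spacing)

    def delta_phi(self, longitude, latitude):
        """True interommatidial angle at a direction, degrees."""
        u = np.asarray(longitude, float)
        v = lambert_v(np.asarray(latitude, float))
        out = np.sqrt(self.p(u) * self.q(v))
        return float(out) if out.ndim == 0 else out

    def density(self, longitude, latitude):
        """True ommatidial density, facets per square degree."""
        d = self.delta_phi(longitude, latitude)
        return 2.0 / (math.sqrt(3.0) * np.asarray(d) ** 2)

    def _antiderivatives(self, lons: np.ndarray, lats: np.ndarray):
        P = {float(u): quad(lambda s: 1.0 / self.p(s), 0.0, float(u))[0]
             for u in lons}
        Q = {float(la): quad(lambda s: 1.0 / self.q(s), 0.0,
                             float(lambert_v(la)))[0]
             for la in lats}
        return P, Q


def gen_facet_observations(field: DensityField,
                           boundary: tuple[tuple[float, float],
                                           tuple[float, float]] = ((-100.0, 100.0),
                                                                   (-80.0, 80.0)),
                           diameter_field=None,
                           directions=None) -> list[FacetObservation]:
    """Generate pseudopupil facet observations on the direction grid.

    For each grid direction inside ``boundary`` (= ((lon_min, lon_max),
    (lat_min, lat_max))), the continuous lattice coordinates of the
    smooth map are rounded to the integer facet the pseudopupil centres
    on.  Directions outside the boundary are omitted with a log entry.
    ``diameter_field`` maps (lon, lat) to a local facet diameter in um
    (default: constant 29 um, an acute-zone vespid facet).
    """
    (lon_min, lon_max), (lat_min, lat_max) = boundary
    step = field.grid_spacing
    if directions is None:
        lons = np.arange(lon_min, lon_max + step / 2, step)
        lats = np.arange(lat_min, lat_max + step / 2, step)
        directions = [(lo, la) for lo in lons for la in lats]

    use_lons = sorted({d[0] for d in directions})
    use_lats = sorted({d[1] for d in directions})
    P, Q = field._antiderivatives(np.asarray(use_lons), np.asarray(use_lats))

    if diameter_field is None:
        diameter_field = lambda lon, lat: 29.0

    out: list[FacetObservation] = []
    for lon, lat in directions:
        if not (lon_min <= lon <= lon_max and lat_min <= lat <= lat_max):
            logger.info("direction (%s, %s) outside visual-field boundary; "
                        "omitted", lon, lat)
            continue
        wx, wy = P[float(lon)], Q[float(lat)]
        # inverse hexagonal basis (spacing 1): det = 2/sqrt(3)
        i = wx - wy / math.sqrt(3.0)
        j = 2.0 * wy / math.sqrt(3.0)
        out.append(FacetObservation(
            longitude=float(lon), latitude=float(lat),
            facet_x=int(round(i)), facet_y=int(round(j)),
            facet_diameter=float(diameter_field(lon, lat))))
    return out
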