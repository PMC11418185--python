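"""Photoreceptor receptive-field estimation.

The workflow mirrors standard intracellular acuity mapping: a dark bar
swept along the four cardinal directions localizes the receptive field
(RF); a dark square drifted line-by-line through a small ROI yields a
gridded hyperpolarization map; and the map is modelled as the 2D
convolution of an elliptical Gaussian angular-sensitivity kernel with the
rendered stimulus target.  A Nelder-Mead simplex search over the kernel's
location, widths and amplitude minimizes the summed squared difference
between model and data.  The acceptance angle is the full width at half
maximum of the fitted kernel,

    delta_rho = 2*sqrt(2*ln 2) * sigma,

reported separately for the horizontal and vertical axes (the vertical
component is the conventional single-number acceptance angle).

Deconvolving the finite target is what distinguishes the fitted kernel
from the raw map: the raw RF is the kernel *blurred* by the target, so its
width always exceeds the true acceptance angle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d
from scipy.optimize import minimize

from .stimulus import StimulusSpec

__all__ = [
    "FWHM_FACTOR",
    "ScreenGeometry",
    "RFLocation",
    "RasterScan",
    "RasterTraces",
    "SweepTrace",
    "BarSweepSet",
    "KernelFit",
    "CentreEstimate",
    "pixel_to_degree",
    "estimate_rf_centre",
    "build_rf_map",
    "render_target",
    "convolve_kernel_with_target",
    "fit_kernel",
    "acceptance_angle",
]

#: FWHM of a Gaussian in units of its standard deviation.
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenGeometry:
    """Flat stimulus screen geometry for the pixel -> degree transform."""

    px_width: int = 1920
    px_height: int = 1080
    width_mm: float = 598.0
    height_mm: float = 336.0
    distance_mm: float = 200.0

    def __post_init__(self) -> None:
        for name in ("px_width", "px_height", "width_mm", "height_mm",
                     "distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def pitch_mm(self) -> tuple[float, float]:
        """Physical pixel pitch (x, y) in mm."""
        return self.width_mm / self.px_width, self.height_mm / self.px_height


@dataclass(frozen=True)
class RFLocation:
    """Receptive-field direction relative to the frontal midpoint, degrees."""

    longitude: float
    latitude: float


@dataclass
class RasterScan:
    """Gridded receptive-field map.

    ``response`` holds the magnitude of the hyperpolarization in mV
    (positive for a dimming response), indexed ``[vertical, horizontal]``
    with angular offsets relative to the ROI centre given by ``x_offsets``
    and ``y_offsets``.
    """

    response: np.ndarray
    x_offsets: np.ndarray
    y_offsets: np.ndarray
    stim: StimulusSpec
    n_repeats: int = 1
    roi_centre: tuple[float, float] = (0.0, 0.0)
    ground_truth: object | None = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.x_offsets = np.asarray(self.x_offsets, dtype=float)
        self.y_offsets = np.asarray(self.y_offsets, dtype=float)
        if self.response.shape != (self.y_offsets.size, self.x_offsets.size):
            raise ValueError(
                f"response shape {self.response.shape} inconsistent with "
                f"{self.y_offsets.size} x {self.x_offsets.size} offset grid")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("response grid contains non-finite values")


@dataclass
class RasterTraces:
    """Line-by-line raster-scan voltage traces before gridding.

    ``data`` columns: time_s, voltage_mV, line_index, repeat, direction.
    Time restarts at 0 for each line; the target enters the ROI after the
    pre-stimulus window.
    """

    data: pd.DataFrame
    stim: StimulusSpec
    direction: str = "lr"  # 'lr': drift left->right; 'tb': top->bottom
    roi_centre: tuple[float, float] = (0.0, 0.0)
    ground_truth: object | None = None


@dataclass
class SweepTrace:
    """One bar-sweep voltage trace.

    ``direction`` names the movement direction of the bar ('left',
    'right', 'up', 'down'); 'right' and 'up' increase screen x and y.
    The bar centre position at time t (after the pre-stimulus window) is
    ``start + velocity * (t - pre_stimulus)`` on its movement axis.
    """

    direction: str
    time: np.ndarray
    voltage: np.ndarray
    start: float
    velocity: float

    AXES = {"left": "h", "right": "h", "up": "v", "down": "v"}

    def __post_init__(self) -> None:
        if self.direction not in self.AXES:
            raise ValueError(f"unknown sweep direction {self.direction!r}")
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.shape != self.voltage.shape:
            raise ValueError("time and voltage must have equal length")

    @property
    def axis(self) -> str:
        return self.AXES[self.direction]


@dataclass
class BarSweepSet:
    """The four cardinal bar sweeps of one cell."""

    traces: dict[str, SweepTrace]
    stim: StimulusSpec
    ground_truth: object | None = None

    def __post_init__(self) -> None:
        for name, tr in self.traces.items():
            if name != tr.direction:
                raise ValueError(f"trace keyed {name!r} has direction "
                                 f"{tr.direction!r}")


@dataclass
class KernelFit:
    """Best-fit convolved-Gaussian kernel parameters.

    ``x0, y0`` locate the kernel centre in ROI coordinates (degrees);
    ``sigma_h, sigma_v`` are the Gaussian SDs; ``amplitude`` is the peak
    hyperpolarization magnitude (mV) the kernel would produce for a fully
    dark, fully resolved stimulus; ``sse`` is the summed squared residual.
    """

    x0: float
    y0: float
    sigma_h: float
    sigma_v: float
    amplitude: float
    sse: float
    converged: bool
    n_evals: int = 0

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be non-negative")
        if self.converged and (self.sigma_h <= 0 or self.sigma_v <= 0):
            raise ValueError("converged fit requires positive sigmas")

    @property
    def delta_rho_h(self) -> float:
        """Horizontal acceptance angle, degrees (FWHM of the kernel)."""
        return FWHM_FACTOR * self.sigma_h

    @property
    def delta_rho_v(self) -> float:
        """Vertical acceptance angle, degrees (FWHM of the kernel)."""
        return FWHM_FACTOR * self.sigma_v

    def to_dict(self) -> dict:
        return {
            "x0": self.x0, "y0": self.y0,
            "sigma_h": self.sigma_h, "sigma_v": self.sigma_v,
            "delta_rho_h": self.delta_rho_h, "delta_rho_v": self.delta_rho_v,
            "amplitude": self.amplitude, "sse": self.sse,
            "converged": self.converged,
        }


@dataclass
class CentreEstimate:
    """RF centre on the screen, from opposing-sweep midpoints.

    Either axis may be unavailable when a sweep direction is missing; the
    corresponding coordinate is then ``None``.
    """

    x: float | None
    y: float | None
    per_direction: dict[str, float] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return self.x is not None and self.y is not None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def pixel_to_degree(px_offset: tuple[float, float],
                    geom: ScreenGeometry = ScreenGeometry()) -> RFLocation:
    """Convert a pixel offset from the screen centre to visual angles.

    The screen is flat and faces the animal at ``distance_mm``, so the
    transform is the tangent correction ``arctan(physical offset /
    distance)`` per axis, not a linear small-angle scaling.
    """
    px_x, px_y = px_offset
    pitch_x, pitch_y = geom.pitch_mm
    mm_x, mm_y = px_x * pitch_x, px_y * pitch_y
    if abs(mm_x) > geom.width_mm / 2 or abs(mm_y) > geom.height_mm / 2:
        raise ValueError(
            f"offset ({mm_x:.1f}, {mm_y:.1f}) mm lies beyond the physical "
            f"screen ({geom.width_mm} x {geom.height_mm} mm)")
    return RFLocation(
        longitude=math.degrees(math.atan2(mm_x, geom.distance_mm)),
        latitude=math.degrees(math.atan2(mm_y, geom.distance_mm)),
    )


def _extremum_position(trace: SweepTrace, stim: StimulusSpec,
                       threshold_mv: float | None) -> float:
    """Bar-centre position at the hyperpolarization extremum of one sweep.

    A wide bar crossing a narrow RF produces a plateaued response whose
    sample-wise minimum is noise-fragile, so the extremum time is taken
    as the midpoint of the two half-depth crossings (located by linear
    interpolation), which is sub-sample accurate and exact for the
    symmetric profiles a straight bar produces.
    """
    order = np.argsort(trace.time, kind="stable")
    t, v = trace.time[order], trace.voltage[order]
    pre = t < stim.pre_stimulus
    baseline = float(np.mean(v[pre])) if np.any(pre) else 0.0
    if threshold_mv is None:
        noise = float(np.std(v[pre])) if np.count_nonzero(pre) > 1 else 0.0
        threshold_mv = 4.0 * noise
    depth = baseline - v
    dmax = float(depth.max())
    if dmax <= threshold_mv or dmax <= 0:
        raise ValueError(
            f"no hyperpolarization above threshold ({threshold_mv:.3g} mV) "
            f"in {trace.direction!r} sweep")

    half = dmax / 2.0
    above = np.flatnonzero(depth >= half)
    lo, hi = int(above[0]), int(above[-1])

    def crossing(inner: int, outer: int) -> float:
        if outer < 0 or outer >= t.size or depth[outer] >= half:
            return float(t[inner])
        frac = (half - depth[outer]) / (depth[inner] - depth[outer])
        return float(t[outer] + frac * (t[inner] - t[outer]))

    t_star = 0.5 * (crossing(lo, lo - 1) + crossing(hi, hi + 1))
    return trace.start + trace.velocity * (t_star - stim.pre_stimulus)


def estimate_rf_centre(sweeps: BarSweepSet,
                       threshold_mv: float | None = None) -> CentreEstimate:
    """Estimate RF centre coordinates from four cardinal bar sweeps.

    Per axis the centre is the midpoint of the two bar positions (position
    = start + velocity x extremum time) obtained from opposing sweep
    directions.  Because the response lags the stimulus by the cell's
    latency tau, each single-direction position is displaced by
    velocity*tau; opposite directions are displaced symmetrically, so the
    midpoint cancels the latency exactly.

    Missing directions leave the corresponding axis estimate ``None``.
    A sweep with no detectable hyperpolarization raises ``ValueError``
    naming the trace.
    """
    per_direction: dict[str, float] = {}
    for name, trace in sweeps.traces.items():
        per_direction[name] = _extremum_position(trace, sweeps.stim,
                                                 threshold_mv)
    x = y = None
    if "left" in per_direction and "right" in per_direction:
        x = 0.5 * (per_direction["left"] + per_direction["right"])
    if "up" in per_direction and "down" in per_direction:
        y = 0.5 * (per_direction["up"] + per_direction["down"])
    return CentreEstimate(x=x, y=y, per_direction=per_direction)


def render_target(target_size: float, x_offsets: np.ndarray,
                  y_offsets: np.ndarray | None = None,
                  centre: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Render the square stimulus target on the raster grid.

    Each cell holds the *area fraction* of that cell covered by the
    target, so edge cells are weighted by partial coverage and the image
    integral (sum x cell area) equals the target area exactly for any
    sub-cell placement of the target.
    """
    if target_size <= 0:
        raise ValueError(f"target_size must be positive, got {target_size}")
    x_offsets = np.asarray(x_offsets, dtype=float)
    y_offsets = x_offsets if y_offsets is None else np.asarray(y_offsets, float)

    def coverage(grid: np.ndarray, c: float) -> np.ndarray:
        step = _uniform_step(grid)
        lo, hi = c - target_size / 2.0, c + target_size / 2.0
        overlap = (np.minimum(hi, grid + step / 2.0)
                   - np.maximum(lo, grid - step / 2.0))
        return np.clip(overlap, 0.0, step) / step

    return np.outer(coverage(y_offsets, centre[1]),
                    coverage(x_offsets, centre[0]))


def _uniform_step(grid: np.ndarray) -> float:
    steps = np.diff(grid)
    if steps.size == 0:
        raise ValueError("grid must have at least two points")
    if not np.allclose(steps, steps[0]):
        raise ValueError("grid must be uniformly spaced")
    return float(steps[0])


def _gaussian_taps(grid: np.ndarray, centre: float, sigma: float) -> np.ndarray:
    """Gaussian sampled on the grid and normalized to unit discrete mass.

    Unit mass (rather than the midpoint-rule ``pdf * cell``) keeps the
    convolution amplitude-preserving in both limits: a kernel much wider
    than a cell behaves as the continuous unit-integral Gaussian, and a
    kernel much narrower than a cell degenerates to a discrete delta.
    """
    z = (grid - centre) / sigma
    t = np.exp(-0.5 * z * z)
    return t / t.sum()


def _model_response(params: np.ndarray, target: np.ndarray,
                    x_offsets: np.ndarray, y_offsets: np.ndarray) -> np.ndarray:
    """Convolved-kernel model evaluated on the raster grid.

    Discrete 2D convolution of the unit-integral elliptical Gaussian with
    the target image, factorized into two 1D passes (the axis-aligned
    Gaussian is separable).  Sigmas enter through their absolute value so
    the simplex can wander through zero without breaking the model.
    """
    x0, y0, sh, sv, amp = params
    sh, sv = abs(sh), abs(sv)
    eps = 1e-6
    gh = _gaussian_taps(x_offsets, x0, max(sh, eps))
    gv = _gaussian_taps(y_offsets, y0, max(sv, eps))
    m = convolve1d(target, gh, axis=1, mode="constant", cval=0.0)
    m = convolve1d(m, gv, axis=0, mode="constant", cval=0.0)
    return amp * m


def convolve_kernel_with_target(kernel_params: tuple[float, float, float,
                                                     float, float],
                                target: np.ndarray,
                                x_offsets: np.ndarray,
                                y_offsets: np.ndarray) -> np.ndarray:
    """Model RF map: elliptical Gaussian kernel convolved with the target.

    ``kernel_params`` is ``(x0, y0, sigma_h, sigma_v, amplitude)``.  The
    Gaussian has unit integral so ``amplitude`` is the response to a fully
    resolved dark target; the output lives on the same ROI grid as
    ``target``.
    """
    x0, y0, sh, sv, amp = kernel_params
    if sh <= 0 or sv <= 0:
        raise ValueError(f"kernel sigmas must be positive, got ({sh}, {sv})")
    target = np.asarray(target, dtype=float)
    x_offsets = np.asarray(x_offsets, dtype=float)
    y_offsets = np.asarray(y_offsets, dtype=float)
    if target.shape != (y_offsets.size, x_offsets.size):
        raise ValueError("target grid incongruent with offset axes")
    return _model_response(np.array([x0, y0, sh, sv, amp]), target,
                           x_offsets, y_offsets)


def _moment_initial_guess(data: np.ndarray, target: np.ndarray,
                          x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Moment-based starting point: peak location, deconvolved SDs, amplitude."""
    iy, ix = np.unravel_index(int(np.argmax(data)), data.shape)
    w = np.clip(data, 0.0, None)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("raster map is degenerate (no positive response)")
    mx = float((w.sum(axis=0) * x).sum() / tot)
    my = float((w.sum(axis=1) * y).sum() / tot)
    vx = float((w.sum(axis=0) * (x - mx) ** 2).sum() / tot)
    vy = float((w.sum(axis=1) * (y - my) ** 2).sum() / tot)
    tx = target.sum(axis=0) / target.sum()
    ty = target.sum(axis=1) / target.sum()
    tvx = float((tx * x ** 2).sum() - ((tx * x).sum()) ** 2)
    tvy = float((ty * y ** 2).sum() - ((ty * y).sum()) ** 2)
    half_cell = _uniform_step(x) / 2.0
    s0h = math.sqrt(max(vx - tvx, half_cell ** 2))
    s0v = math.sqrt(max(vy - tvy, half_cell ** 2))
    unit = _model_response(np.array([x[ix], y[iy], s0h, s0v, 1.0]),
                           target, x, y)
    amp0 = float(data.max() / max(unit.max(), 1e-12))
    return np.array([x[ix], y[iy], s0h, s0v, amp0])


def fit_kernel(raster: RasterScan, *, isotropic: bool = False,
               n_starts: int = 5, xatol: float = 1e-4,
               maxfev: int = 2000, min_snr: float = 3.0) -> KernelFit:
    """Fit the convolved-Gaussian kernel to a raster map by simplex search.

    Nelder-Mead minimizes the summed squared difference between the
    convolved model and the observed map over (x0, y0, sigma_h, sigma_v,
    amplitude) -- or a single shared sigma when ``isotropic=True``.  The
    search restarts from the raster peak and the four cells one step away
    (``n_starts`` of these five starts are used) to guard against local
    minima; the best SSE wins.

    Raises ``ValueError`` for a flat map or one whose peak does not clear
    ``min_snr`` times the robust noise estimate.  Non-convergence within
    the evaluation budget is reported through ``converged`` rather than
    raised; the best parameters found are still returned.
    """
    data = raster.response
    x, y = raster.x_offsets, raster.y_offsets
    if np.ptp(data) == 0:
        raise ValueError("raster map is flat; nothing to fit")
    noise = 1.4826 * float(np.median(np.abs(data - np.median(data))))
    peak = float(data.max())
    if noise > 0 and peak < min_snr * noise:
        raise ValueError(
            f"raster peak ({peak:.3g} mV) below {min_snr} x noise floor "
            f"({noise:.3g} mV)")

    target = render_target(raster.stim.target_size, x, y)
    p0 = _moment_initial_guess(data, target, x, y)
    step = _uniform_step(x)
    shifts = [(0.0, 0.0), (step, 0.0), (-step, 0.0), (0.0, step), (0.0, -step)]

    if isotropic:
        def unpack(q: np.ndarray) -> np.ndarray:
            return np.array([q[0], q[1], q[2], q[2], q[3]])
        starts = [np.array([p0[0] + dx, p0[1] + dy,
                            0.5 * (p0[2] + p0[3]), p0[4]])
                  for dx, dy in shifts[:n_starts]]
    else:
        def unpack(q: np.ndarray) -> np.ndarray:
            return q
        starts = [np.array([p0[0] + dx, p0[1] + dy, p0[2], p0[3], p0[4]])
                  for dx, dy in shifts[:n_starts]]

    def objective(q: np.ndarray) -> float:
        return float(np.sum((_model_response(unpack(q), target, x, y)
                             - data) ** 2))

    best = None
    n_evals = 0
    for q0 in starts:
        res = minimize(objective, q0, method="Nelder-Mead",
                       options={"xatol": xatol, "fatol": 1e-12,
                                "maxfev": maxfev})
        n_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    p = unpack(best.x)
    return KernelFit(x0=float(p[0]), y0=float(p[1]),
                     sigma_h=float(abs(p[2])), sigma_v=float(abs(p[3])),
                     amplitude=float(p[4]), sse=float(best.fun),
                     converged=bool(best.success), n_evals=n_evals)


def acceptance_angle(fit: KernelFit) -> float:
    """Acceptance angle delta_rho in degrees: the vertical kernel FWHM."""
    if not fit.converged:
        warnings.warn("kernel fit did not converge; acceptance angle may be "
                      "unreliable", stacklevel=2)
    return fit.delta_rho_v


def build_rf_map(traces: RasterTraces, stim: StimulusSpec | None = None
                 ) -> RasterScan:
    """Grid line-by-line raster traces into a receptive-field map.

    Each (repeat, line) trace has its mean pre-stimulus voltage
    subtracted, post-stimulus samples are assigned to raster cells by the
    target position implied by the drift speed, repeats are averaged
    pointwise, and the hyperpolarization is stored as a positive
    magnitude.
    """
    stim = stim or traces.stim
    if traces.direction not in ("lr", "tb"):
        raise ValueError(f"unknown drift direction {traces.direction!r}")
    df = traces.data
    required = {"time_s", "voltage_mV", "line_index"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace table needs columns {sorted(required)}")
    if "repeat" not in df.columns:
        df = df.assign(repeat=0)

    offs = stim.offsets()
    n = offs.size
    spacing = stim.spacing
    start = offs[0]
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n), dtype=int)

    expected_len: int | None = None
    for (rep, line), g in df.groupby(["repeat", "line_index"], sort=True):
        line = int(line)
        if not 0 <= line < n:
            raise ValueError(f"line_index {line} outside 0..{n - 1}")
        g = g.sort_values("time_s", kind="stable")
        if expected_len is None:
            expected_len = len(g)
        elif len(g) != expected_len:
            raise ValueError(
                f"inconsistent trace length at line {line} (repeat {rep}): "
                f"{len(g)} vs {expected_len}")
        t = g["time_s"].to_numpy()
        v = g["voltage_mV"].to_numpy()
        pre = t < stim.pre_stimulus
        baseline = float(v[pre].mean()) if pre.any() else 0.0
        v = v - baseline
        post = ~pre
        pos = start + stim.drift_speed * (t[post] - stim.pre_stimulus)
        cell = np.rint((pos - start) / spacing).astype(int)
        ok = (cell >= 0) & (cell < n)
        for c, val in zip(cell[ok], v[post][ok]):
            if traces.direction == "lr":
                acc[line, c] += val
                cnt[line, c] += 1
            else:  # 'tb': lines are columns, drift runs down the rows
                acc[n - 1 - c, line] += val
                cnt[n - 1 - c, line] += 1

    grid = np.zeros((n, n))
    seen = cnt > 0
    grid[seen] = -acc[seen] / cnt[seen]
    return RasterScan(response=grid, x_offsets=offs, y_offsets=offs,
                      stim=stim, n_repeats=int(df["repeat"].nunique()),
                      roi_centre=traces.roi_centre,
                      ground_truth=traces.ground_truth)
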