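"""Interommatidial-angle mapping from pseudopupil facet coordinates.

At every 10-deg step of longitude and latitude, pseudopupil imaging yields
the integer lattice coordinates (facet rows x, y relative to an origin
facet) of the facet looking straight back at the viewer, plus the local
facet diameter D.  The facet-coordinate field is a smooth map from viewing
direction to the ommatidial lattice; its Jacobian determinant with respect
to *solid angle* is the local ommatidial density rho (facets per square
degree), and for a hexagonal lattice with centre spacing delta_phi the
cell area is (sqrt(3)/2) * delta_phi**2, so

    rho = 2 / (sqrt(3) * delta_phi**2)      <=>
    delta_phi = sqrt(2 / (sqrt(3) * rho)).

Two density estimators are provided.  ``local_density`` fits a local
affine map (a per-node Jacobian) over a 3x3 neighbourhood of grid
directions, with longitude steps scaled by cos(latitude) so displacements
are true arc degrees.  ``build_eye_map`` instead defaults to fitting one
smooth polynomial surface per facet coordinate over the whole sampled
field, expressed in Lambert cylindrical equal-area coordinates
(longitude, (180/pi)*sin(latitude)) where the Jacobian determinant is
directly facets per square degree; the polynomial degree is chosen by BIC.
The global fit is strongly preferred because the observed coordinates are
integers: rounding a smooth map to whole facets injects +/-0.5-facet
quantization noise that per-node differencing amplifies, while a surface
fitted to the full grid averages it away.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon
from skimage import measure

__all__ = [
    "FacetObservation",
    "EyeMapGrid",
    "ContourLine",
    "local_density",
    "density_to_delta_phi",
    "delta_phi_to_density",
    "build_eye_map",
    "interpolate_isolines",
    "lambert_v",
]

logger = logging.getLogger(__name__)

SQRT3 = math.sqrt(3.0)
DEG = 180.0 / math.pi


def lambert_v(latitude_deg):
    """Equal-area latitude coordinate v = (180/pi) * sin(latitude).

    (longitude, v) is the Lambert cylindrical equal-area chart of the
    direction sphere scaled to degrees: a unit of area in this chart is
    one true square degree, which is what makes Jacobian determinants in
    it read directly as facets per square degree.
    """
    return DEG * np.sin(np.radians(latitude_deg))


@dataclass(frozen=True)
class FacetObservation:
    """Pseudopupil-centre facet at one viewing direction.

    ``facet_x, facet_y`` are integer lattice row coordinates relative to
    the origin facet at (0 deg, 0 deg); ``facet_diameter`` is the local
    average facet diameter in um.
    """

    longitude: float
    latitude: float
    facet_x: int
    facet_y: int
    facet_diameter: float = float("nan")


@dataclass
class EyeMapGrid:
    """Per-direction ommatidial density, delta_phi and facet diameter.

    2D layers are indexed ``[latitude, longitude]`` on the regular
    direction grid given by ``lons`` and ``lats``; missing or flagged
    nodes hold NaN.  ``boundary`` is the visual-field boundary polygon as
    an (N, 2) array of (longitude, latitude) vertices.
    """

    lons: np.ndarray
    lats: np.ndarray
    density: np.ndarray
    delta_phi: np.ndarray
    diameter: np.ndarray
    boundary: np.ndarray
    flags: dict[tuple[float, float], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (len(self.lats), len(self.lons))
        for name in ("density", "delta_phi", "diameter"):
            layer = np.asarray(getattr(self, name), dtype=float)
            if layer.shape != shape:
                raise ValueError(f"{name} layer shape {layer.shape} != {shape}")
            setattr(self, name, layer)
        finite = self.delta_phi[np.isfinite(self.delta_phi)]
        if finite.size and np.any(finite <= 0):
            raise ValueError("delta_phi must be positive where defined")

    def argmin_delta_phi(self) -> tuple[float, float]:
        """Grid direction (lon, lat) of the smallest interommatidial angle."""
        masked = np.where(np.isfinite(self.delta_phi), self.delta_phi, np.inf)
        i, j = np.unravel_index(int(np.argmin(masked)), masked.shape)
        return float(self.lons[j]), float(self.lats[i])

    def to_dataframe(self) -> pd.DataFrame:
        lon_g, lat_g = np.meshgrid(self.lons, self.lats)
        return pd.DataFrame({
            "longitude_deg": lon_g.ravel(),
            "latitude_deg": lat_g.ravel(),
            "density_per_deg2": self.density.ravel(),
            "delta_phi_deg": self.delta_phi.ravel(),
            "facet_diameter_um": self.diameter.ravel(),
        })


@dataclass(frozen=True)
class ContourLine:
    """One iso-line polyline in (longitude, latitude) degrees."""

    level: float
    vertices: np.ndarray  # (N, 2) lon, lat


# ---------------------------------------------------------------------------
# Density estimators
# ---------------------------------------------------------------------------

def local_density(observations: list[FacetObservation],
                  lon0: float, lat0: float,
                  window_deg: float = 10.0) -> float:
    """Local ommatidial density from a per-node affine Jacobian fit.

    Least-squares fits facet_x and facet_y as affine functions of the
    angular displacement from (lon0, lat0), with longitude offsets scaled
    by cos(lat0) to arc degrees, over all observations within one grid
    step (up to a 3x3 window).  Returns the Jacobian determinant, which is
    the density in facets per square degree for a properly oriented
    lattice; a non-positive value indicates lattice fold-over and should
    be flagged by the caller.

    Raises ``ValueError`` when fewer than three non-collinear directions
    are available.
    """
    rows, fx, fy = [], [], []
    for ob in observations:
        dlo, dla = ob.longitude - lon0, ob.latitude - lat0
        if abs(dlo) <= window_deg + 1e-9 and abs(dla) <= window_deg + 1e-9:
            rows.append([1.0, dlo * math.cos(math.radians(lat0)), dla])
            fx.append(ob.facet_x)
            fy.append(ob.facet_y)
    A = np.asarray(rows)
    if len(rows) < 3 or np.linalg.matrix_rank(A) < 3:
        raise ValueError(
            f"fewer than 3 non-collinear observations around "
            f"({lon0}, {lat0})")
    cx = np.linalg.lstsq(A, np.asarray(fx, float), rcond=None)[0]
    cy = np.linalg.lstsq(A, np.asarray(fy, float), rcond=None)[0]
    return float(cx[1] * cy[2] - cx[2] * cy[1])


def density_to_delta_phi(rho) -> float | np.ndarray:
    """Interommatidial angle from areal density, hexagonal-lattice convention.

    A hexagonal lattice with centre spacing delta_phi tiles the sphere in
    cells of area (sqrt(3)/2)*delta_phi**2, hence
    delta_phi = sqrt(2/(sqrt(3)*rho)).
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be strictly positive")
    out = np.sqrt(2.0 / (SQRT3 * rho))
    return float(out) if out.ndim == 0 else out


def delta_phi_to_density(delta_phi) -> float | np.ndarray:
    """Inverse of :func:`density_to_delta_phi`: rho = 2/(sqrt(3)*dphi^2)."""
    delta_phi = np.asarray(delta_phi, dtype=float)
    if np.any(delta_phi <= 0):
        raise ValueError("delta_phi must be strictly positive")
    out = 2.0 / (SQRT3 * delta_phi ** 2)
    return float(out) if out.ndim == 0 else out


class _PolySurface:
    """Bivariate polynomial least-squares surfaces for both facet coordinates.

    One shared total degree, selected by BIC over 1..max_degree, fitted in
    scaled (longitude, lambert_v) coordinates.  Residual structure beyond
    the polynomial is dominated by the +/-0.5 rounding of facet counts, so
    BIC's conservative penalty keeps the degree low for simple eyes.
    """

    def __init__(self, lons, lats, fx, fy, max_degree: int = 6):
        u = np.asarray(lons, float)
        v = lambert_v(np.asarray(lats, float))
        self.su = max(np.abs(u).max(), 1.0)
        self.sv = max(np.abs(v).max(), 1.0)
        U, V = u / self.su, v / self.sv
        fx = np.asarray(fx, float)
        fy = np.asarray(fy, float)
        n = fx.size
        best = None
        for deg in range(1, max_degree + 1):
            terms = [(a, b) for a in range(deg + 1)
                     for b in range(deg + 1 - a)]
            if len(terms) + 2 >= n:
                break
            A = np.stack([U ** a * V ** b for a, b in terms], axis=1)
            cx = np.linalg.lstsq(A, fx, rcond=None)[0]
            cy = np.linalg.lstsq(A, fy, rcond=None)[0]
            rss = float(np.sum((A @ cx - fx) ** 2)
                        + np.sum((A @ cy - fy) ** 2))
            m = 2 * n
            bic = m * math.log(max(rss, 1e-12) / m) + 2 * len(terms) * math.log(m)
            if best is None or bic < best[0]:
                best = (bic, deg, terms, cx, cy)
        _, self.degree, self.terms, self.cx, self.cy = best

    def jacobian_det(self, lon, lat):
        """det d(facet_x, facet_y)/d(area) in facets per square degree."""
        u = np.asarray(lon, float) / self.su
        v = lambert_v(np.asarray(lat, float)) / self.sv
        j11 = j12 = j21 = j22 = 0.0
        for c_x, c_y, (a, b) in zip(self.cx, self.cy, self.terms):
            if a > 0:
                du = a * u ** (a - 1) * v ** b / self.su
                j11 = j11 + c_x * du
                j21 = j21 + c_y * du
            if b > 0:
                dv = b * u ** a * v ** (b - 1) / self.sv
                j12 = j12 + c_x * dv
                j22 = j22 + c_y * dv
        # (lon, lambert_v) is equal-area, so this determinant already is
        # per true square degree; no cos(latitude) factor remains.
        return j11 * j22 - j12 * j21


# ---------------------------------------------------------------------------
# Map construction
# ---------------------------------------------------------------------------

def build_eye_map(observations: list[FacetObservation], *,
                  method: str = "surface", max_degree: int = 6,
                  boundary: np.ndarray | None = None) -> EyeMapGrid:
    """Build density / delta_phi / facet-diameter maps from observations.

    Observations must lie on a regular (longitude, latitude) grid; one
    observation per direction.  ``method='surface'`` (default) estimates
    density from global polynomial coordinate surfaces, ``method='local'``
    from per-node 3x3 affine Jacobians.  Nodes where estimation fails or
    the Jacobian is non-positive are flagged and set to NaN.
    """
    if method not in ("surface", "local"):
        raise ValueError(f"unknown method {method!r}")
    seen: dict[tuple[float, float], FacetObservation] = {}
    dups = []
    for ob in observations:
        key = (float(ob.longitude), float(ob.latitude))
        if key in seen:
            dups.append(key)
        seen[key] = ob
    if dups:
        raise ValueError(f"duplicate directions: {sorted(set(dups))}")

    lons = np.unique([k[0] for k in seen])
    lats = np.unique([k[1] for k in seen])
    for axis, name in ((lons, "longitude"), (lats, "latitude")):
        if axis.size > 2 and not np.allclose(np.diff(axis), np.diff(axis)[0]):
            raise ValueError(f"{name} values do not form a regular grid")

    shape = (lats.size, lons.size)
    density = np.full(shape, np.nan)
    diameter = np.full(shape, np.nan)
    flags: dict[tuple[float, float], str] = {}

    if method == "surface":
        obs = list(seen.values())
        surf = _PolySurface([o.longitude for o in obs],
                            [o.latitude for o in obs],
                            [o.facet_x for o in obs],
                            [o.facet_y for o in obs],
                            max_degree=max_degree)
        for i, la in enumerate(lats):
            for j, lo in enumerate(lons):
                if (lo, la) not in seen:
                    flags[(lo, la)] = "missing"
                    continue
                det = float(surf.jacobian_det(lo, la))
                if det <= 0:
                    flags[(lo, la)] = "fold-over"
                    logger.warning("non-positive Jacobian at (%s, %s)", lo, la)
                else:
                    density[i, j] = det
    else:
        step = float(np.diff(lons)[0]) if lons.size > 1 else 10.0
        obs = list(seen.values())
        for i, la in enumerate(lats):
            for j, lo in enumerate(lons):
                if (lo, la) not in seen:
                    flags[(lo, la)] = "missing"
                    continue
                try:
                    det = local_density(obs, lo, la, window_deg=step)
                except ValueError:
                    flags[(lo, la)] = "insufficient-neighbourhood"
                    continue
                if det <= 0:
                    flags[(lo, la)] = "fold-over"
                else:
                    density[i, j] = det

    for i, la in enumerate(lats):
        for j, lo in enumerate(lons):
            ob = seen.get((lo, la))
            if ob is not None:
                diameter[i, j] = ob.facet_diameter

    delta_phi = np.full(shape, np.nan)
    ok = np.isfinite(density)
    delta_phi[ok] = density_to_delta_phi(density[ok])

    if boundary is None:
        boundary = np.array([
            (lons.min(), lats.min()), (lons.max(), lats.min()),
            (lons.max(), lats.max()), (lons.min(), lats.max()),
            (lons.min(), lats.min()),
        ])
    return EyeMapGrid(lons=lons, lats=lats, density=density,
                      delta_phi=delta_phi, diameter=diameter,
                      boundary=np.asarray(boundary, float), flags=flags)


# ---------------------------------------------------------------------------
# Iso-line interpolation
# ---------------------------------------------------------------------------

def _fill_nan_nearest(values: np.ndarray) -> np.ndarray:
    """Fill NaN nodes from the nearest valid node (for contouring only)."""
    if not np.any(np.isnan(values)):
        return values
    from scipy.interpolate import griddata
    ii, jj = np.indices(values.shape)
    ok = np.isfinite(values)
    if not ok.any():
        raise ValueError("no valid nodes to contour")
    filled = values.copy()
    filled[~ok] = griddata((ii[ok], jj[ok]), values[ok],
                           (ii[~ok], jj[~ok]), method="nearest")
    return filled


def interpolate_isolines(grid: EyeMapGrid, levels,
                         layer: str = "delta_phi") -> list[ContourLine]:
    """Marching-squares iso-contours of a map layer.

    Contours are traced in (longitude, latitude) space on the node grid
    (missing nodes are filled from their nearest neighbour for tracing
    only), clipped to the visual-field boundary polygon, and returned as
    polylines with vertices in degrees.  Levels outside the data range
    simply yield no contours.
    """
    values = getattr(grid, layer)
    values = np.asarray(values, float)
    if min(values.shape) < 2:
        raise ValueError("need at least a 2x2 grid to contour")
    filled = _fill_nan_nearest(values)
    poly = Polygon(grid.boundary)
    out: list[ContourLine] = []
    for level in np.atleast_1d(levels):
        for path in measure.find_contours(filled, float(level)):
            lon = np.interp(path[:, 1], np.arange(grid.lons.size), grid.lons)
            lat = np.interp(path[:, 0], np.arange(grid.lats.size), grid.lats)
            line = LineString(np.column_stack([lon, lat]))
            clipped = line.intersection(poly)
            geoms = getattr(clipped, "geoms", [clipped])
            for g in geoms:
                if g.is_empty or g.geom_type != "LineString":
                    continue
                out.append(ContourLine(level=float(level),
                                       vertices=np.asarray(g.coords)))
    return out
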