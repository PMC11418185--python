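"""Ommatidial optics: white-light sensitivity, diffraction limit, rhabdom subtense.

The optical sensitivity of an apposition ommatidium in broad-spectrum
("white") light is computed in the Kirschfeld/Land form

    S = (pi/4)^2 * D^2 * (d/f)^2 * k*l / (2.3 + k*l)      [um^2 sr]

where ``D`` is the facet diameter, ``f`` the focal length, ``d`` and ``l``
the rhabdom diameter and length (all in um) and ``k`` the rhabdom's
broadband absorption coefficient (um^-1).  The last factor is the fraction
of entering light absorbed over a rhabdom of length ``l``; the constant 2.3
(= ln 10) arises from averaging absorption over a broad spectrum.

Two simple diffraction/geometry figures accompany it: the angular
half-width of the Airy disk, lambda/D radians, which bounds the optical
resolution of a facet of aperture ``D``, and the geometric angular subtense
of the rhabdom tip, d/f radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "OmmatidiumOptics",
    "optical_sensitivity",
    "airy_halfwidth",
    "rhabdom_subtense",
    "VESPULA_GERMANICA",
    "VESPULA_VULGARIS",
]

#: Broad-spectrum absorption constant of the white-light sensitivity formula
#: (ln 10, from decadic absorbance averaged over the spectrum).
LN10 = 2.3


def _require_positive(**params: float) -> None:
    for name, value in params.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class OmmatidiumOptics:
    """Morphological parameters of one ommatidium.

    Parameters
    ----------
    D : float
        Facet (lens) diameter, um.
    f : float
        Focal length of the ommatidial optics, um.  Default 67 um,
        the value measured for *Vespula* ommatidia.
    d : float
        Rhabdom diameter, um.
    l : float
        Rhabdom length, um.
    k : float
        Broadband absorption coefficient of the rhabdom, um^-1.
        Default 0.0067 um^-1, the standard insect value.
    wavelength : float
        Wavelength used for the diffraction figure, um.  Default 0.53 um
        (green light).
    """

    D: float
    d: float
    l: float
    f: float = 67.0
    k: float = 0.0067
    wavelength: float = 0.53
    label: str = ""

    def __post_init__(self) -> None:
        _require_positive(D=self.D, d=self.d, l=self.l, f=self.f,
                          wavelength=self.wavelength)
        if self.k < 0 or not math.isfinite(self.k):
            raise ValueError(f"k must be non-negative, got {self.k!r}")

    @property
    def sensitivity(self) -> float:
        return optical_sensitivity(self)

    @property
    def airy_halfwidth_deg(self) -> float:
        return airy_halfwidth(self.wavelength, self.D)[1]

    @property
    def rhabdom_subtense_deg(self) -> float:
        return rhabdom_subtense(self.d, self.f)[1]


def optical_sensitivity(o: OmmatidiumOptics) -> float:
    """White-light optical sensitivity S of one ommatidium, in um^2 sr.

    Monotonically increasing in D, d and l; for k*l -> infinity it
    approaches the fully-absorbing limit (pi/4)^2 D^2 (d/f)^2, and for
    k = 0 (a transparent rhabdom) it is exactly zero.
    """
    absorbed = o.k * o.l / (LN10 + o.k * o.l)
    return (math.pi / 4.0) ** 2 * o.D ** 2 * (o.d / o.f) ** 2 * absorbed


def airy_halfwidth(wavelength: float, D: float) -> tuple[float, float]:
    """Angular half-width of the Airy disk, lambda/D.

    Parameters are in the same length unit (conventionally um).  Returns
    ``(radians, degrees)``.
    """
    _require_positive(wavelength=wavelength, D=D)
    rad = wavelength / D
    return rad, math.degrees(rad)


def rhabdom_subtense(d: float, f: float) -> tuple[float, float]:
    """Geometric angular size of the rhabdom tip, d/f.

    Returns ``(radians, degrees)``.
    """
    _require_positive(d=d, f=f)
    rad = d / f
    return rad, math.degrees(rad)


#: Acute-zone morphology of the two study species (facet diameter at the
#: acute-zone centre, shared focal length, rhabdom dimensions from TEM).
VESPULA_GERMANICA = OmmatidiumOptics(D=29.0, d=2.1, l=227.0,
                                     label="V. germanica")
VESPULA_VULGARIS = OmmatidiumOptics(D=26.0, d=1.9, l=255.0,
                                    label="V. vulgaris")
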