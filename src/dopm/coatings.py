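"""Thin-film complex reflectivity of coated fold mirrors.

Reflection coefficients for s and p polarization are computed with the
characteristic (transfer) matrix method through an ordered stack of
dielectric/metal layers onto a substrate.  The sign convention is the usual
Fresnel one in which ``r_s == r_p`` at normal incidence.

Stacks are described from the substrate outward, so ``layers[-1]`` is the
layer the light meets first.  The incident medium is assumed lossless
(default: air).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoatingStack",
    "coating_reflectivity",
    "default_stack",
    "DEFAULT_WAVELENGTH_NM",
]

#: Default simulation wavelength, mid-band of the green emission window.
DEFAULT_WAVELENGTH_NM = 520.0

# refractive indices near 520 nm; coatings are configurable because exact
# manufacturer specifications are generally unavailable
N_SILVER = 0.13 + 3.19j
N_ALUMINUM = 0.93 + 6.33j
N_SIO2 = 1.461
N_SIO = 1.97


@dataclass(frozen=True)
class CoatingStack:
    """A layered mirror: substrate index plus (index, thickness-nm) layers
    listed from the substrate outward.

    The special name ``"perfect"`` denotes an ideal mirror with |r| = 1 and
    no s/p phase splitting; it bypasses the transfer-matrix computation.
    """

    substrate_index: complex
    layers: tuple[tuple[complex, float], ...] = field(default_factory=tuple)
    name: str = "custom"

    def __post_init__(self) -> None:
        for _, d in self.layers:
            if d < 0:
                raise ValueError("layer thicknesses must be non-negative")

    @property
    def is_perfect(self) -> bool:
        return self.name == "perfect"


_DEFAULTS = {
    "perfect": CoatingStack(substrate_index=1e9j, layers=(), name="perfect"),
    "bare_silver": CoatingStack(substrate_index=N_SILVER, layers=(), name="bare_silver"),
    "silver_sio2": CoatingStack(
        substrate_index=N_SILVER, layers=((N_SIO2, 100.0),), name="silver_sio2"
    ),
    "aluminum_sio": CoatingStack(
        substrate_index=N_ALUMINUM, layers=((N_SIO, 100.0),), name="aluminum_sio"
    ),
}


def default_stack(name: str) -> CoatingStack:
    """Look up one of the built-in stacks:
    perfect | bare_silver | silver_sio2 | aluminum_sio."""
    try:
        return _DEFAULTS[name]
    except KeyError:
        raise ValueError(
            f"unknown coating {name!r}; expected one of {sorted(_DEFAULTS)}"
        ) from None


def coating_reflectivity(
    stack: CoatingStack,
    incidence_deg: float | np.ndarray,
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
    polarization: str = "s",
    n_incident: float = 1.0,
) -> complex | np.ndarray:
    """Complex amplitude reflection coefficient of a coated mirror.

    Parameters
    ----------
    stack : CoatingStack
        Layer description (substrate outward).
    incidence_deg : float or array
        Angle of incidence in the incident medium, degrees, in [0, 90).
    wavelength_nm : float
        Vacuum wavelength.
    polarization : {"s", "p"}
        Field component perpendicular / parallel to the plane of incidence.
    n_incident : float
        Real index of the incident medium.
    """
    if polarization not in ("s", "p"):
        raise ValueError("polarization must be 's' or 'p'")
    if np.iscomplexobj(np.asarray(n_incident)) or n_incident <= 0:
        raise ValueError("absorbing or non-physical incident medium unsupported")
    theta = np.radians(np.asarray(incidence_deg, dtype=float))
    if np.any(theta < 0) or np.any(theta >= math.pi / 2):
        raise ValueError("incidence angle must be in [0, 90) degrees")

    if stack.is_perfect:
        r = -np.ones_like(theta, dtype=complex)
        return r if r.shape else complex(r)

    # transverse wavevector is conserved; kz in each medium from Snell
    kx = n_incident * np.sin(theta)

    def cos_in(n: complex) -> np.ndarray:
        # principal branch decays into absorbing media for Im(n) >= 0
        return np.sqrt(n**2 - kx**2 + 0j) / n

    def admittance(n: complex, c: np.ndarray) -> np.ndarray:
        return n * c if polarization == "s" else n / c

    eta0 = admittance(n_incident, np.cos(theta))
    c_sub = cos_in(stack.substrate_index)
    b = np.ones_like(theta, dtype=complex)
    c = admittance(stack.substrate_index, c_sub) * b

    # build up from the substrate through each layer
    for n_j, d_j in stack.layers:
        cj = cos_in(n_j)
        etaj = admittance(n_j, cj)
        delta = 2 * math.pi * n_j * cj * d_j / wavelength_nm
        cosd, sind = np.cos(delta), np.sin(delta)
        # n + ik indices with exp(-i omega t): characteristic matrix carries -i
        b, c = cosd * b - 1j * sind / etaj * c, -1j * etaj * sind * b + cosd * c

    r = (eta0 * b - c) / (eta0 * b + c)
    return r if r.shape else complex(r)
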