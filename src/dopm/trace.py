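"""Vectorial (Jones) ray tracing of the folded dual-view collection path.

Each ray carries a propagation direction and a complex transverse electric
field, both as lab-frame 3-vectors.  High-NA lenses rotate the field in the
meridional plane (the rotation that carries the ray direction onto the lens
axis), waveplates and polarizer ports act in lab Cartesian coordinates, and
the tilted fold mirror reflects the direction with a Householder matrix and
applies the coating's complex s/p reflectivities in the per-ray s/p basis.

Because every element downstream of the emitter is linear and
dipole-independent, the whole path collapses to one composed 3x3 complex
operator per ray.  Ensemble sums over dipole orientations then reduce to
3x3 Gram matrices, so the default 15,000-ray x 7,500-dipole simulation runs
in well under a second.

The collection path is: O1 collimation -> (polarization-neutral relay) ->
PBS transmit port -> quarter-wave plate -> O2 focus -> coated tilted mirror
-> O3 collimation -> quarter-wave plate (second pass) -> PBS reflect port.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from dopm.coatings import (
    DEFAULT_WAVELENGTH_NM,
    CoatingStack,
    coating_reflectivity,
    default_stack,
)
from dopm.config import SystemGeometry
from dopm.geometry import fibonacci_sphere, half_angle, mirror_normal_tilt

__all__ = [
    "Ray",
    "DipoleEmitter",
    "PupilField",
    "EfficiencyReport",
    "RayChain",
    "low_na_double_pass_transmission",
    "fibonacci_directions",
    "build_ray_fan",
    "dipole_ensemble",
    "dipole_farfield",
    "meridional_matrix",
    "waveplate_matrix",
    "polarizer_matrix",
    "mirror_matrices",
    "element_jones",
    "precompute_chain",
    "ensemble_efficiency",
    "pupil_map",
]

DEFAULT_N_RAYS = 15_000
DEFAULT_N_DIPOLES = 7_500

# lab axes: z is the O1/O2 optical axis; the mirror tilts in the x-z plane.
_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])
# PBS transmit axis and the in-sheet excitation axis are both lab x.
PBS_TRANSMIT_AXIS = _X
PBS_REFLECT_AXIS = _Y
QWP_FAST_AXIS = np.array([1.0, 1.0, 0.0]) / math.sqrt(2.0)


@dataclass
class Ray:
    """A single traced ray: unit wavevector plus complex transverse field."""

    k_hat: np.ndarray
    e_field: np.ndarray
    pupil_coords: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        k = np.asarray(self.k_hat, dtype=float)
        e = np.asarray(self.e_field, dtype=complex)
        if abs(np.linalg.norm(k) - 1.0) > 1e-9:
            raise ValueError("k_hat must be a unit vector")
        norm = np.linalg.norm(e)
        if norm > 0 and abs(k @ e) > 1e-9 * norm:
            raise ValueError("e_field must be transverse to k_hat")
        self.k_hat, self.e_field = k, e


@dataclass(frozen=True)
class DipoleEmitter:
    """A fixed electric dipole orientation with a photoselection weight."""

    d_hat: np.ndarray
    weight: float

    def __post_init__(self) -> None:
        d = np.asarray(self.d_hat, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("d_hat must be a unit vector")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        object.__setattr__(self, "d_hat", d)


@dataclass
class PupilField:
    """Binned intensity over normalized tertiary-pupil coordinates."""

    intensity: np.ndarray  # (bins, bins), arbitrary units
    extent: tuple[float, float, float, float]  # (-1, 1, -1, 1) in NA units

    @property
    def total_energy(self) -> float:
        return float(self.intensity.sum())


@dataclass(frozen=True)
class EfficiencyReport:
    """Collection efficiency of the folded path relative to the primary
    objective alone."""

    fraction_vs_o1: float
    regime: str
    includes_t_optics: bool
    opm_angle_deg: float
    coating: str


def low_na_double_pass_transmission(anisotropy: float) -> float:
    """Analytic paraxial PBS/QWP double-pass transmission for emission with
    the given steady-state anisotropy.

    With r = (I_par - I_perp) / (I_par + 2 I_perp), the fraction of the
    transverse (detected) intensity polarized along the excitation axis is
    (1 + 2r) / (2 + r): 0.50 for fully depolarized emission (r = 0) and
    0.75 for the static photoselection limit (r = 0.4).
    """
    if not -0.2 <= anisotropy <= 0.4:
        raise ValueError("steady-state anisotropy must be in [-0.2, 0.4]")
    return (1 + 2 * anisotropy) / (2 + anisotropy)


def fibonacci_directions(n: int, cap_half_angle_deg: float = 180.0) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors in a cap about +z
    (golden-angle spiral)."""
    return fibonacci_sphere(n, cap_half_angle_deg)


def build_ray_fan(
    geometry: SystemGeometry, n: int = DEFAULT_N_RAYS
) -> tuple[np.ndarray, np.ndarray]:
    """Hemispherical fan of ray directions overfilling the primary pupil.

    Returns ``(directions, inside_o1)``: an (n, 3) array and a boolean mask
    marking rays within the primary collection cone.
    """
    dirs = fibonacci_directions(n, 90.0)
    a1 = half_angle(geometry.primary.na, geometry.primary.immersion_index)
    inside = dirs[:, 2] >= math.cos(math.radians(a1)) - 1e-12
    return dirs, inside


def dipole_ensemble(
    n: int = DEFAULT_N_DIPOLES,
    regime: str = "tumbling",
    excitation_polarization: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Hemisphere-filling dipole orientations with per-regime weights.

    Orientations come from the Fibonacci spiral (a dipole and its negation
    are equivalent, so a hemisphere covers all orientations).  In the
    ``tumbling`` regime all weights are equal; in the ``static`` regime each
    dipole is weighted by cos^2 of its angle to the linear excitation
    polarization (photoselection).
    """
    if regime not in ("tumbling", "static"):
        raise ValueError(f"unknown regime {regime!r}")
    d = fibonacci_directions(n, 90.0)
    if regime == "tumbling":
        w = np.ones(n)
    else:
        e = PBS_TRANSMIT_AXIS if excitation_polarization is None else np.asarray(
            excitation_polarization, dtype=float
        )
        norm = np.linalg.norm(e)
        if norm == 0:
            raise ValueError("excitation polarization must be non-zero")
        w = (d @ (e / norm)) ** 2
    return d, w


def dipole_farfield(d_hat: np.ndarray, k_hat: np.ndarray) -> np.ndarray:
    """Far-field dipole emission: the transverse projection of the dipole
    axis, E proportional to k x (d x k)."""
    d = np.asarray(d_hat, dtype=float)
    k = np.asarray(k_hat, dtype=float)
    return d - (d @ k) * k


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Batched Rodrigues rotations carrying unit vectors u onto v.

    ``u`` and ``v`` broadcast to (n, 3); returns (n, 3, 3).  Antiparallel
    pairs are not expected on the collection path and raise.
    """
    u = np.atleast_2d(u)
    v = np.atleast_2d(v)
    u, v = np.broadcast_arrays(u, v)
    c = np.einsum("ij,ij->i", u, v)
    if np.any(c < -1 + 1e-12):
        raise ValueError("antiparallel rotation is ill-defined")
    w = np.cross(u, v)  # axis * sin(angle)
    n = len(u)
    eye = np.broadcast_to(np.eye(3), (n, 3, 3))
    wx = np.zeros((n, 3, 3))
    wx[:, 0, 1], wx[:, 0, 2] = -w[:, 2], w[:, 1]
    wx[:, 1, 0], wx[:, 1, 2] = w[:, 2], -w[:, 0]
    wx[:, 2, 0], wx[:, 2, 1] = -w[:, 1], w[:, 0]
    # R = I + [w]x + [w]x^2 / (1 + c)
    return eye + wx + wx @ wx / (1.0 + c)[:, None, None]


def meridional_matrix(k_in: np.ndarray, k_out: np.ndarray) -> np.ndarray:
    """Lens meridional transform: rotate the field with its ray from k_in to
    k_out (collimation when k_out is the axis, focusing when k_in is)."""
    return _rotation_between(k_in, k_out)


def waveplate_matrix(
    k_hat: np.ndarray, fast_axis: np.ndarray, retardance_rad: float
) -> np.ndarray:
    """Retarder acting on the transverse plane of rays travelling along
    +/-z (lab Cartesian element)."""
    f = np.asarray(fast_axis, dtype=float)
    f = f / np.linalg.norm(f)
    g = np.cross(np.asarray(k_hat, dtype=float), f)
    return np.outer(f, f) + np.exp(1j * retardance_rad) * np.outer(g, g)


def polarizer_matrix(axis: np.ndarray) -> np.ndarray:
    """Ideal linear polarizer / PBS port: projector onto a lab axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    return np.outer(a, a).astype(complex)


def mirror_matrices(
    k_in: np.ndarray,
    normal: np.ndarray,
    stack: CoatingStack,
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
) -> tuple[np.ndarray, np.ndarray]:
    """Coated-mirror reflection for a batch of rays.

    Returns ``(k_out, M)`` where ``k_out`` is the Householder-reflected
    direction ``(I - 2 n n^T) k`` and ``M`` the (n, 3, 3) complex operator
    applying the stack's ``r_s``/``r_p`` in each ray's s/p basis.  For the
    ``perfect`` stack M reduces to ``2 n n^T - I`` (unit reflectivity, no
    s/p splitting).
    """
    nrm = np.asarray(normal, dtype=float)
    if abs(np.linalg.norm(nrm) - 1.0) > 1e-9:
        raise ValueError("mirror normal must be a unit vector")
    k_in = np.atleast_2d(k_in)
    cos_inc = -(k_in @ nrm)
    if np.any(cos_inc <= 0):
        raise ValueError("rays must hit the mirror front face")
    k_out = k_in - 2.0 * (k_in @ nrm)[:, None] * nrm

    if stack.is_perfect:
        m = 2.0 * np.outer(nrm, nrm) - np.eye(3)
        return k_out, np.broadcast_to(m.astype(complex), (len(k_in), 3, 3))

    inc_deg = np.degrees(np.arccos(np.clip(cos_inc, -1.0, 1.0)))
    r_s = np.asarray(coating_reflectivity(stack, inc_deg, wavelength_nm, "s"))
    r_p = np.asarray(coating_reflectivity(stack, inc_deg, wavelength_nm, "p"))

    s = np.cross(k_in, np.broadcast_to(nrm, k_in.shape))
    s_norm = np.linalg.norm(s, axis=1, keepdims=True)
    # near-normal incidence: s/p degenerate, any transverse basis works
    degenerate = s_norm[:, 0] < 1e-9
    if np.any(degenerate):
        fallback = np.cross(k_in[degenerate], _X)
        tiny = np.linalg.norm(fallback, axis=1) < 1e-9
        fallback[tiny] = np.cross(k_in[degenerate][tiny], _Y)
        s[degenerate] = fallback
        s_norm = np.linalg.norm(s, axis=1, keepdims=True)
    s = s / s_norm
    p_in = np.cross(s, k_in)
    p_out = np.cross(s, k_out)

    # Fresnel convention (r_s == r_p at normal incidence):
    # E' = r_s (s.E) s - r_p (p_in.E) p_out
    m = r_s[:, None, None] * np.einsum("ni,nj->nij", s, s) - r_p[
        :, None, None
    ] * np.einsum("ni,nj->nij", p_out, p_in)
    return k_out, m


def element_jones(element: str, ray: Ray, **kwargs) -> Ray:
    """Apply a single named element to one ray (convenience wrapper around
    the vectorized matrix builders).

    ``element`` is one of ``lens`` (kwargs: ``axis``, ``mode`` =
    collimate|focus, ``k_target`` for focus), ``waveplate`` (``fast_axis``,
    ``retardance_rad``), ``polarizer`` (``axis``) or ``mirror`` (``normal``,
    ``stack``, ``wavelength_nm``).
    """
    k = ray.k_hat[None, :]
    if element == "lens":
        axis = np.asarray(kwargs["axis"], dtype=float)
        if kwargs.get("mode", "collimate") == "collimate":
            m = meridional_matrix(k, axis[None, :])[0]
            k_new = axis
        else:
            k_target = np.asarray(kwargs["k_target"], dtype=float)
            m = meridional_matrix(axis[None, :], k_target[None, :])[0]
            k_new = k_target
        return Ray(k_new, m @ ray.e_field, ray.pupil_coords)
    if element == "waveplate":
        m = waveplate_matrix(ray.k_hat, kwargs["fast_axis"], kwargs["retardance_rad"])
        return Ray(ray.k_hat, m @ ray.e_field, ray.pupil_coords)
    if element == "polarizer":
        m = polarizer_matrix(kwargs["axis"])
        return Ray(ray.k_hat, m @ ray.e_field, ray.pupil_coords)
    if element == "mirror":
        stack = kwargs.get("stack", default_stack("perfect"))
        k_out, m = mirror_matrices(
            k, kwargs["normal"], stack, kwargs.get("wavelength_nm", DEFAULT_WAVELENGTH_NM)
        )
        return Ray(k_out[0], m[0] @ ray.e_field, ray.pupil_coords)
    raise ValueError(f"unknown element {element!r}")


@dataclass
class RayChain:
    """Precomputed per-ray operators for the full collection path."""

    directions: np.ndarray  # (n, 3) sample-space ray directions
    inside_o1: np.ndarray  # (n,) bool
    alive: np.ndarray  # (n,) bool: inside O1 and not vignetted downstream
    operators: np.ndarray  # (n, 3, 3) complex: dipole far-field -> O3 pupil
    pupil_xy: np.ndarray  # (n, 2) normalized tertiary pupil coordinates
    geometry: SystemGeometry

    @property
    def o1_projectors(self) -> np.ndarray:
        """(n, 3, 3) transverse projectors I - k k^T for the fan."""
        k = self.directions
        return np.eye(3) - np.einsum("ni,nj->nij", k, k)


def precompute_chain(
    geometry: SystemGeometry,
    n_rays: int = DEFAULT_N_RAYS,
    stack: CoatingStack | None = None,
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
    include_pbs_qwp: bool = True,
) -> RayChain:
    """Compose the per-ray Jones chain from emitter to the tertiary pupil.

    Tube and relay optics are polarization-neutral and drop out; the chain
    is O1 (meridional), PBS transmit, QWP, O2 (meridional), coated tilted
    mirror, O3 (meridional), QWP, PBS reflect.  Rays vignetted by the O2 or
    O3 aperture, or outside O1, get a zero operator.  With
    ``include_pbs_qwp=False`` the polarizing elements are omitted (ideal
    unfolded reference for energy-conservation checks).
    """
    if stack is None:
        stack = default_stack(geometry.coating)
    k_all, inside_o1 = build_ray_fan(geometry, n_rays)
    n = len(k_all)
    # rays outside the primary cone never propagate; trace only the rest
    # (grazing out-of-cone rays could even miss the tilted mirror face)
    k = k_all[inside_o1]
    a23 = half_angle(
        geometry.secondary_tertiary.na, geometry.secondary_tertiary.immersion_index
    )
    cos_a23 = math.cos(math.radians(a23))
    tilt = math.radians(mirror_normal_tilt(geometry.opm_angle_deg))
    normal = np.array([math.sin(tilt), 0.0, -math.cos(tilt)])

    # O1 collimation (ray angles are preserved into remote space by the
    # remote-refocusing magnification, so the same k parametrizes both)
    r1 = meridional_matrix(k, _Z)
    # O2 refocus toward the mirror
    r2 = meridional_matrix(np.broadcast_to(_Z, k.shape), k)
    k_refl, m_mirror = mirror_matrices(k, normal, stack, wavelength_nm)
    # O3 collimation about the return axis -z
    r3 = meridional_matrix(k_refl, -_Z)

    mid = r3 @ m_mirror @ r2
    if include_pbs_qwp:
        qwp_fwd = waveplate_matrix(_Z, QWP_FAST_AXIS, math.pi / 2)
        qwp_back = waveplate_matrix(-_Z, QWP_FAST_AXIS, math.pi / 2)
        pre = qwp_fwd @ polarizer_matrix(PBS_TRANSMIT_AXIS)
        post = polarizer_matrix(PBS_REFLECT_AXIS) @ qwp_back
        sub_ops = post @ mid @ (pre @ r1)
    else:
        sub_ops = mid @ r1

    vignetted = (k[:, 2] < cos_a23) | (-k_refl[:, 2] < cos_a23)
    sub_ops[vignetted] = 0.0

    ops = np.zeros((n, 3, 3), dtype=complex)
    ops[inside_o1] = sub_ops
    alive = np.zeros(n, dtype=bool)
    alive[inside_o1] = ~vignetted
    pupil_xy = np.zeros((n, 2))
    pupil_xy[inside_o1] = k_refl[:, :2] / geometry.secondary_tertiary.na
    return RayChain(
        directions=k_all,
        inside_o1=inside_o1,
        alive=alive,
        operators=ops,
        pupil_xy=pupil_xy,
        geometry=geometry,
    )


def _gram_matrices(chain: RayChain) -> tuple[np.ndarray, np.ndarray]:
    """(G, G0): sums over rays of A^H A (traced path) and of the transverse
    projector (light collected by O1)."""
    proj = chain.o1_projectors
    a = chain.operators @ proj
    g = np.einsum("nij,nik->jk", a.conj(), a)
    g0 = proj[chain.inside_o1].sum(axis=0).astype(complex)
    return g, g0


def ensemble_efficiency(
    geometry: SystemGeometry,
    regime: str = "tumbling",
    include_t_optics: bool = False,
    n_rays: int = DEFAULT_N_RAYS,
    n_dipoles: int = DEFAULT_N_DIPOLES,
    stack: CoatingStack | None = None,
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
    chain: RayChain | None = None,
) -> EfficiencyReport:
    """Ensemble collection efficiency of the folded path relative to O1.

    Incoherent sum over dipole orientations and rays of the pupil-plane
    energy, divided by the energy the primary objective collects from the
    same ensemble.  Optionally scaled by the measured optics transmission
    T_optics = T_O2/3^2 * T_PBS.
    """
    if n_dipoles < 1:
        raise ValueError("dipole ensemble must be non-empty")
    if chain is None:
        chain = precompute_chain(geometry, n_rays, stack, wavelength_nm)
    d, w = dipole_ensemble(n_dipoles, regime)
    g, g0 = _gram_matrices(chain)
    num = float(np.einsum("ni,ij,nj,n->", d, g.real, d, w))
    den = float(np.einsum("ni,ij,nj,n->", d, g0.real, d, w))
    frac = num / den
    if include_t_optics:
        t23 = geometry.secondary_tertiary.single_pass_transmission
        frac *= t23**2 * geometry.t_pbs
    stack_name = stack.name if stack is not None else geometry.coating
    return EfficiencyReport(
        fraction_vs_o1=frac,
        regime=regime,
        includes_t_optics=include_t_optics,
        opm_angle_deg=geometry.opm_angle_deg,
        coating=stack_name,
    )


def pupil_map(
    geometry: SystemGeometry,
    regime: str = "tumbling",
    n_rays: int = DEFAULT_N_RAYS,
    n_dipoles: int = DEFAULT_N_DIPOLES,
    bins: int = 64,
    stack: CoatingStack | None = None,
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
) -> PupilField:
    """Dipole-summed intensity binned over the normalized tertiary pupil.

    The map integrates exactly to ``ensemble_efficiency x O1-collected
    energy`` (energy bookkeeping) with the same sampling.
    """
    if bins < 8:
        raise ValueError("bins must be >= 8")
    chain = precompute_chain(geometry, n_rays, stack, wavelength_nm)
    d, w = dipole_ensemble(n_dipoles, regime)
    # second moment of the weighted dipole distribution
    dmat = np.einsum("ni,nj,n->ij", d, d, w)
    a = chain.operators @ chain.o1_projectors
    per_ray = np.einsum("nij,jk,nik->n", a.conj(), dmat, a).real

    xy = chain.pupil_xy[chain.alive]
    hist, _, _ = np.histogram2d(
        xy[:, 0],
        xy[:, 1],
        bins=bins,
        range=[[-1, 1], [-1, 1]],
        weights=per_ray[chain.alive],
    )
    return PupilField(intensity=hist, extent=(-1.0, 1.0, -1.0, 1.0))
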