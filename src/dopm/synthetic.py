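"""Deterministic generators for every input the toolkit consumes.

Bead phantoms (sparse sub-resolution emitters blurred by an anisotropic,
optionally tilted Gaussian PSF with Poisson photon noise, Gaussian read
noise and a background pedestal), thin fluorescent sheets, sheared dual-view
oblique acquisitions of a lab-frame ground truth, and exponentially
bleaching ROI time series.  Every generator takes a mandatory seed and is
reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dopm.volume import LabVolume, RawObliqueStack, forward_skew

__all__ = [
    "PhantomSpec",
    "make_bead_phantom",
    "make_oblique_acquisition",
    "make_sheet_phantom",
    "make_bleach_series",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a bead phantom.

    ``bead_fwhm_um`` is (x, y, z); ``psf_tilt_deg`` tilts the PSF's z axis
    in the y-z plane (skewed detection PSF).
    """

    shape_um: tuple[float, float, float] = (15.0, 15.0, 15.0)  # (z, y, x)
    voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.1)
    n_beads: int = 30
    bead_fwhm_um: tuple[float, float, float] = (0.29, 0.31, 0.83)
    psf_tilt_deg: float = 0.0
    background: float = 10.0
    peak_photons: float = 1000.0
    min_separation_um: float = 3.0
    border_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape_um) <= 0 or min(self.voxel_size_um) <= 0:
            raise ValueError("sizes must be positive")
        for f, v in zip(self.bead_fwhm_um, self.voxel_size_um[::-1]):
            if f < 2 * v:
                raise ValueError(
                    "bead FWHMs must span at least 2 voxels for recovery tests"
                )


def _place_beads(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Seeded non-overlapping positions (um, z/y/x) away from the border."""
    lo = np.full(3, spec.border_um)
    hi = np.array(spec.shape_um) - spec.border_um
    if np.any(hi <= lo):
        raise ValueError("volume too small for the requested border margin")
    positions: list[np.ndarray] = []
    attempts = 0
    max_attempts = 2000 * max(spec.n_beads, 1)
    while len(positions) < spec.n_beads:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "bead density too high to satisfy the separation constraint"
            )
        p = rng.uniform(lo, hi)
        if all(
            np.linalg.norm(p - q) >= spec.min_separation_um for q in positions
        ):
            positions.append(p)
    return np.array(positions).reshape(spec.n_beads, 3)


def make_bead_phantom(spec: PhantomSpec) -> tuple[LabVolume, pd.DataFrame]:
    """Render a noisy bead phantom and its ground-truth table."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(
        int(round(s / v)) + 1 for s, v in zip(spec.shape_um, spec.voxel_size_um)
    )
    clean = np.zeros(shape)
    positions = _place_beads(spec, rng)

    fx, fy, fz = spec.bead_fwhm_um
    sig = np.array([fz, fy, fx]) / (2 * math.sqrt(2 * math.log(2)))  # (z, y, x)
    tilt = math.radians(spec.psf_tilt_deg)
    half = np.ceil(4 * sig / np.array(spec.voxel_size_um)).astype(int)

    for p in positions:
        center_idx = p / np.array(spec.voxel_size_um)
        lo = np.maximum(np.floor(center_idx - half).astype(int), 0)
        hi = np.minimum(np.ceil(center_idx + half).astype(int) + 1, shape)
        grids = np.meshgrid(
            *[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij"
        )
        d = [
            (g - c) * v
            for g, c, v in zip(grids, center_idx, spec.voxel_size_um)
        ]  # um offsets (z, y, x)
        if tilt:
            dz = d[0] * math.cos(tilt) - d[1] * math.sin(tilt)
            dy = d[0] * math.sin(tilt) + d[1] * math.cos(tilt)
            d = [dz, dy, d[2]]
        expo = sum((di / s) ** 2 for di, s in zip(d, sig))
        patch = spec.peak_photons * np.exp(-0.5 * expo)
        clean[tuple(slice(a, b) for a, b in zip(lo, hi))] += patch

    clean += spec.background
    noisy = rng.poisson(clean).astype(float)
    truth = pd.DataFrame(
        positions, columns=["z_um", "y_um", "x_um"]
    ).assign(fwhm_x=fx, fwhm_y=fy, fwhm_z=fz, peak_photons=spec.peak_photons)
    return LabVolume(noisy, spec.voxel_size_um), truth


def make_oblique_acquisition(
    lab_volume: LabVolume,
    opm_angle_deg: float,
    scan_step_um: float | None = None,
    pixel_row_um: float | None = None,
    pixel_col_um: float | None = None,
    noise_rms: float = 0.0,
    seed: int = 0,
) -> tuple[RawObliqueStack, RawObliqueStack]:
    """Sheared dual-view stacks of a common ground-truth volume.

    Sampling defaults to the lab voxel size (rows scaled so the tilted rows
    cover the axial extent).  Optional independent Gaussian noise per view.
    """
    vz, vy, vx = lab_volume.voxel_size_um
    th = math.radians(opm_angle_deg)
    scan_step_um = vy if scan_step_um is None else scan_step_um
    pixel_row_um = vz / math.sin(th) if pixel_row_um is None else pixel_row_um
    pixel_col_um = vx if pixel_col_um is None else pixel_col_um

    rng = np.random.default_rng(seed)
    stacks = []
    for view in (1, 2):
        raw = forward_skew(
            lab_volume, opm_angle_deg, view, scan_step_um, pixel_row_um, pixel_col_um
        )
        if noise_rms > 0:
            raw.voxels = raw.voxels + rng.normal(0, noise_rms, raw.voxels.shape)
        stacks.append(raw)
    return stacks[0], stacks[1]


def make_sheet_phantom(
    fwhm_um: float = 3.0,
    tilt_deg: float = 0.0,
    noise_rms: float = 0.0,
    shape_um: tuple[float, float, float] = (20.0, 10.0, 10.0),
    voxel_size_um: tuple[float, float, float] = (0.25, 0.5, 0.5),
    peak: float = 100.0,
    seed: int = 0,
) -> LabVolume:
    """Thin fluorescent sheet: Gaussian axial profile, optionally tilted in
    the x-z plane, spanning the field of view."""
    if fwhm_um <= 0:
        raise ValueError("fwhm must be positive")
    shape = tuple(int(round(s / v)) + 1 for s, v in zip(shape_um, voxel_size_um))
    z = np.arange(shape[0])[:, None, None] * voxel_size_um[0]
    x = np.arange(shape[2])[None, None, :] * voxel_size_um[2]
    z0 = shape_um[0] / 2 + math.tan(math.radians(tilt_deg)) * (x - shape_um[2] / 2)
    vol = peak * np.exp(-4 * math.log(2) * (z - z0) ** 2 / fwhm_um**2)
    vol = np.broadcast_to(vol, shape).copy()
    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        vol += rng.normal(0, noise_rms, shape)
    return LabVolume(vol, voxel_size_um)


def make_bleach_series(
    rates_per_s: np.ndarray,
    n_timepoints: int = 50,
    dt_s: float = 60.0,
    noise_rms: float = 0.0,
    seed: int = 0,
    initial_intensity: float = 1000.0,
) -> np.ndarray:
    """Exponentially bleaching ROI time series I(t) = I0 exp(-k t) + noise.

    Returns an (n_rois, n_timepoints) array."""
    rates = np.atleast_1d(np.asarray(rates_per_s, dtype=float))
    if np.any(rates < 0):
        raise ValueError("bleach rates must be non-negative")
    t = np.arange(n_timepoints) * dt_s
    series = initial_intensity * np.exp(-rates[:, None] * t[None, :])
    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        series = series + rng.normal(0, noise_rms, series.shape)
    return series
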