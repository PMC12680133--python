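"""Deskew, registration and fusion of dual-view oblique stacks.

A raw stack indexes (scan frame i, camera row r, camera column c).  The
camera plane is tilted by the oblique angle about the scan axis, so voxel
(i, r, c) sits at lab coordinates::

    x = c * pixel_col
    y = i * scan_step + s * r * pixel_row * cos(theta)
    z = r * pixel_row * sin(theta)

with s = +1 for view 1 and s = -1 for view 2 (the two views shear in
opposite senses).  Lab z is distance from the coverslip.  Deskewing
resamples onto an axis-aligned grid by trilinear interpolation; the forward
model samples a lab volume along the tilted camera planes and is the
generator used for synthetic acquisitions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "RawObliqueStack",
    "LabVolume",
    "RigidTransform",
    "deskew",
    "forward_skew",
    "register_views",
    "fuse",
    "read_volume",
    "write_volume",
]


@dataclass
class RawObliqueStack:
    """Per-view sheared acquisition: (scan frame, camera row, camera column)."""

    voxels: np.ndarray
    scan_step_um: float
    pixel_row_um: float
    pixel_col_um: float
    opm_angle_deg: float
    view_id: int = 1

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("raw stack must be 3D (frame, row, column)")
        if min(self.scan_step_um, self.pixel_row_um, self.pixel_col_um) <= 0:
            raise ValueError("sampling intervals must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("raw stack contains non-finite intensities")
        if self.view_id not in (1, 2):
            raise ValueError("view_id must be 1 or 2")

    @property
    def shear_sign(self) -> int:
        return 1 if self.view_id == 1 else -1


@dataclass
class LabVolume:
    """Axis-aligned volume; voxels indexed (z, y, x) with sizes in um."""

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]  # (z, y, x)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("lab volume must be 3D (z, y, x)")
        if min(self.voxel_size_um) <= 0:
            raise ValueError("voxel sizes must be positive")


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion between registered views: rotation fixed by geometry,
    residual translation estimated from the data (um)."""

    translation_um: tuple[float, float, float]  # (z, y, x)
    rotation: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )
    confidence: float = 1.0

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8) or not math.isclose(
            np.linalg.det(r), 1.0, abs_tol=1e-8
        ):
            raise ValueError("rotation must be orthonormal with det +1")

    def to_json(self) -> str:
        return json.dumps(
            {
                "translation_um": list(self.translation_um),
                "rotation": np.asarray(self.rotation).tolist(),
                "confidence": self.confidence,
            }
        )


def _scan_origin(raw: RawObliqueStack) -> float:
    """Lab-y of scan frame 0, camera row 0.

    Convention: both views sweep the same lab-frame y range, so the frame
    count needed to cover a volume is shear-independent and the two
    deskewed views land on identical grids.  View 1 shears rows toward +y
    and starts its scan shifted back by the full row footprint; view 2
    shears toward -y and starts at 0.
    """
    nr = raw.voxels.shape[1]
    th = math.radians(raw.opm_angle_deg)
    footprint = (nr - 1) * raw.pixel_row_um * math.cos(th)
    return -footprint if raw.shear_sign > 0 else 0.0


def _lab_bounds(raw: RawObliqueStack) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """((zmin, ymin, xmin), (zmax, ymax, xmax)) in um swept by the planes."""
    ni, nr, nc = raw.voxels.shape
    th = math.radians(raw.opm_angle_deg)
    footprint = (nr - 1) * raw.pixel_row_um * math.cos(th)
    zmax = (nr - 1) * raw.pixel_row_um * math.sin(th)
    ymin = -footprint  # identical for both shear signs under _scan_origin
    ymax = (ni - 1) * raw.scan_step_um
    xmax = (nc - 1) * raw.pixel_col_um
    return (0.0, ymin, 0.0), (zmax, ymax, xmax)


def _default_voxel_size(raw: RawObliqueStack) -> float:
    th = math.radians(raw.opm_angle_deg)
    return min(raw.pixel_row_um * math.sin(th), raw.pixel_col_um)


def deskew(
    raw: RawObliqueStack,
    voxel_size_um: float | tuple[float, float, float] | None = None,
) -> LabVolume:
    """Resample a sheared oblique stack onto an axis-aligned lab grid.

    Inverse-maps every output voxel to fractional raw-stack indices and
    interpolates trilinearly; coordinates outside the swept region are
    zero-filled.
    """
    th_deg = raw.opm_angle_deg
    if not 0 < th_deg <= 90:
        raise ValueError("opm angle must be in (0, 90] degrees")
    th = math.radians(th_deg)
    s = raw.shear_sign

    if voxel_size_um is None:
        v = _default_voxel_size(raw)
        voxel_size = (v, v, v)
    elif np.isscalar(voxel_size_um):
        voxel_size = (float(voxel_size_um),) * 3
    else:
        voxel_size = tuple(float(v) for v in voxel_size_um)

    (zmin, ymin, xmin), (zmax, ymax, xmax) = _lab_bounds(raw)
    shape = tuple(
        int(math.floor((hi - lo) / v)) + 1
        for lo, hi, v in zip((zmin, ymin, xmin), (zmax, ymax, xmax), voxel_size)
    )
    z_axis = zmin + np.arange(shape[0]) * voxel_size[0]
    y_axis = ymin + np.arange(shape[1]) * voxel_size[1]
    x_axis = xmin + np.arange(shape[2]) * voxel_size[2]
    y_start = _scan_origin(raw)

    # chunk over z so coordinate arrays never exceed a few output slabs
    out = np.empty(shape)
    chunk = max(1, int(4e6 // max(shape[1] * shape[2], 1)))
    for k0 in range(0, shape[0], chunk):
        zz, yy, xx = np.meshgrid(
            z_axis[k0 : k0 + chunk], y_axis, x_axis, indexing="ij"
        )
        r_idx = zz / (raw.pixel_row_um * math.sin(th))
        c_idx = xx / raw.pixel_col_um
        i_idx = (
            yy - y_start - s * r_idx * raw.pixel_row_um * math.cos(th)
        ) / raw.scan_step_um
        out[k0 : k0 + chunk] = ndimage.map_coordinates(
            raw.voxels,
            np.stack([i_idx, r_idx, c_idx]),
            order=1,
            mode="grid-constant",
            cval=0.0,
        )
    return LabVolume(out, voxel_size, origin_um=(zmin, ymin, xmin))


def forward_skew(
    lab: LabVolume,
    opm_angle_deg: float,
    view_id: int,
    scan_step_um: float,
    pixel_row_um: float,
    pixel_col_um: float,
    n_frames: int | None = None,
    n_rows: int | None = None,
) -> RawObliqueStack:
    """Sample a lab volume along tilted camera planes at successive scan
    positions (adjoint of :func:`deskew`; used by the synthetic generator)."""
    if not 0 < opm_angle_deg <= 90:
        raise ValueError("opm angle must be in (0, 90] degrees")
    th = math.radians(opm_angle_deg)
    s = 1 if view_id == 1 else -1
    vz, vy, vx = lab.voxel_size_um
    nz, ny, nx = lab.voxels.shape

    if n_rows is None:
        n_rows = int(math.floor((nz - 1) * vz / (pixel_row_um * math.sin(th)))) + 1
    footprint = (n_rows - 1) * pixel_row_um * math.cos(th)
    if n_frames is None:
        # every row's scan must sweep the full y extent of the volume
        n_frames = int(math.floor(((ny - 1) * vy + footprint) / scan_step_um)) + 1
    nc = int(math.floor((nx - 1) * vx / pixel_col_um)) + 1

    y_start = -footprint if s > 0 else 0.0
    vals = np.empty((n_frames, n_rows, nc))
    chunk = max(1, int(4e6 // max(n_rows * nc, 1)))
    for f0 in range(0, n_frames, chunk):
        i, r, c = np.meshgrid(
            np.arange(f0, min(f0 + chunk, n_frames)),
            np.arange(n_rows),
            np.arange(nc),
            indexing="ij",
        )
        z = r * pixel_row_um * math.sin(th)
        y = y_start + i * scan_step_um + s * r * pixel_row_um * math.cos(th)
        x = c * pixel_col_um
        vals[f0 : f0 + chunk] = ndimage.map_coordinates(
            lab.voxels,
            np.stack([z / vz, y / vy, x / vx]),
            order=1,
            mode="grid-constant",
            cval=0.0,
        )
    return RawObliqueStack(
        vals, scan_step_um, pixel_row_um, pixel_col_um, opm_angle_deg, view_id
    )


def register_views(
    v1: LabVolume,
    v2: LabVolume,
    upsample_factor: int = 20,
    confidence_threshold: float = 0.1,
) -> RigidTransform:
    """Residual translation between two deskewed views by phase correlation.

    The rotation between views is fixed by the known geometry, so only a
    translation is estimated; the correlation peak is refined to sub-voxel
    precision.  A weak normalized peak sets ``confidence`` below the
    threshold rather than raising, flagging a low-confidence registration.
    """
    if v1.voxels.shape != v2.voxels.shape or v1.voxel_size_um != v2.voxel_size_um:
        raise ValueError("views must share one grid; deskew to a common grid first")
    shift, error, _ = phase_cross_correlation(
        v1.voxels, v2.voxels, upsample_factor=upsample_factor, normalization=None
    )
    confidence = float(max(0.0, 1.0 - error))
    if confidence < confidence_threshold:
        import warnings

        warnings.warn("weak correlation peak: low-confidence registration")
    translation = tuple(float(sh * vs) for sh, vs in zip(shift, v1.voxel_size_um))
    return RigidTransform(translation_um=translation, confidence=confidence)


def _apply_translation(vol: LabVolume, transform: RigidTransform) -> np.ndarray:
    shift_voxels = [
        t / vs for t, vs in zip(transform.translation_um, vol.voxel_size_um)
    ]
    if all(abs(s) < 1e-12 for s in shift_voxels):
        return vol.voxels
    return ndimage.shift(vol.voxels, shift_voxels, order=1, mode="constant", cval=0.0)


def fuse(
    v1: LabVolume,
    v2: LabVolume,
    transform: RigidTransform | None = None,
    weights: tuple[float, float] = (0.5, 0.5),
) -> LabVolume:
    """Weighted mean of two registered views on a common grid.

    ``transform`` (from :func:`register_views`) is applied to view 2 before
    averaging; weights default to an unweighted mean.
    """
    if v1.voxels.shape != v2.voxels.shape or v1.voxel_size_um != v2.voxel_size_um:
        raise ValueError("views must share one grid")
    w1, w2 = weights
    total = w1 + w2
    moved = _apply_translation(v2, transform) if transform is not None else v2.voxels
    fused = (w1 * v1.voxels + w2 * moved) / total
    return LabVolume(fused, v1.voxel_size_um, v1.origin_um)


def write_volume(path: str | Path, volume: LabVolume) -> None:
    """Write a lab volume as OME-TIFF with voxel sizes in the metadata."""
    vz, vy, vx = volume.voxel_size_um
    tifffile.imwrite(
        str(path),
        volume.voxels.astype(np.float32),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": vz,
            "PhysicalSizeY": vy,
            "PhysicalSizeX": vx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )


def read_volume(path: str | Path) -> LabVolume:
    """Read an OME-TIFF volume; falls back to unit voxel size when the
    metadata lacks physical sizes."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        sizes = [1.0, 1.0, 1.0]
        if tif.ome_metadata:
            import re

            for axis_i, key in enumerate(("Z", "Y", "X")):
                m = re.search(rf'PhysicalSize{key}="([\d.eE+-]+)"', tif.ome_metadata)
                if m:
                    sizes[axis_i] = float(m.group(1))
    return LabVolume(np.asarray(data, dtype=float), tuple(sizes))
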