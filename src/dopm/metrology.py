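"""PSF and optical-sectioning metrology on bead and sheet volumes, plus the
relative-collection-efficiency and photobleaching statistics.

Beads are detected as isolated local maxima, measured by 1D Gaussian fits
along the lab axes through the sub-voxel centroid, and summarized by median,
IQR and a distribution-free 95% confidence interval on the median.
Sectioning strength is the FWHM of the axial profile of the laterally
integrated bead signal, or of per-column fits through a thin fluorescent
sheet.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, special, stats

from dopm.volume import LabVolume

__all__ = [
    "BeadRecord",
    "BeadSummary",
    "RelativeEfficiencyMeasurement",
    "detect_beads",
    "measure_fwhm",
    "measure_bead",
    "measure_volume",
    "bead_sectioning",
    "sheet_sectioning",
    "summarize",
    "percent_change",
    "airy_encircled_energy",
    "airy_radius",
    "relative_efficiency",
    "photobleach_stats",
]

SIGMA_TO_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548


@dataclass
class BeadRecord:
    """Per-bead measurements in the lab frame (um)."""

    centroid_um: tuple[float, float, float]  # (z, y, x)
    fwhm_x: float = np.nan
    fwhm_y: float = np.nan
    fwhm_z: float = np.nan
    sectioning_fwhm: float = np.nan
    fit_r2: tuple[float, float, float] = (np.nan, np.nan, np.nan)
    included: bool = True
    exclusion_reason: str = ""


@dataclass
class BeadSummary:
    """Median / IQR / 95% CI summary of one metric over included beads."""

    metric: str
    n: int
    median: float
    iqr: float
    ci95: tuple[float, float]


@dataclass
class RelativeEfficiencyMeasurement:
    """Background-corrected signal ratio between matched image pairs."""

    s_dopm: float
    b_dopm: float
    s_epi: float
    b_epi: float
    roi_half_px: int

    @property
    def eta(self) -> float:
        return (self.s_dopm - self.b_dopm) / (self.s_epi - self.b_epi)


# ---------------------------------------------------------------------------
# bead detection and measurement


def detect_beads(
    volume: LabVolume,
    min_separation_um: float = 3.0,
    snr_threshold: float = 8.0,
    border_um: float | None = None,
) -> list[dict]:
    """Isolated local maxima above a robust noise threshold.

    Returns candidate dicts with voxel index, um position and an
    ``included``/``reason`` flag.  Candidates closer than the separation are
    all excluded as ``crowded``; those nearer than ``border_um`` to the
    volume edge as ``border``.
    """
    v = volume.voxels
    vz, vy, vx = volume.voxel_size_um
    # zero-filled margins (deskewed volumes) would bias the noise estimate;
    # fall back to the full volume when almost everything is zero
    nonzero = v[v != 0]
    data = nonzero if nonzero.size >= 0.05 * v.size else v.ravel()
    bg = float(np.median(data))
    noise = float(stats.median_abs_deviation(data, axis=None, scale="normal"))
    threshold = bg + snr_threshold * max(noise, 1e-12)

    # local-maximum window smaller than the isolation distance, so close
    # pairs are still detected and then pruned as crowded
    size = tuple(
        max(3, int(round(0.5 * min_separation_um / s)) | 1)
        for s in volume.voxel_size_um
    )
    footprint_max = ndimage.maximum_filter(v, size=size, mode="constant")
    peaks = np.argwhere((v == footprint_max) & (v > threshold))
    if len(peaks) == 0:
        return []

    pos_um = peaks * np.array([vz, vy, vx])
    candidates = []
    if border_um is None:
        border_um = min_separation_um / 2
    extent = (np.array(v.shape) - 1) * np.array([vz, vy, vx])
    for idx, p in zip(peaks, pos_um):
        cand = {"index": tuple(int(i) for i in idx), "position_um": tuple(p),
                "included": True, "reason": ""}
        if np.any(p < border_um) or np.any(extent - p < border_um):
            cand["included"] = False
            cand["reason"] = "border"
        candidates.append(cand)

    # mutual isolation: any pair closer than min_separation excludes both
    d2 = np.sum((pos_um[:, None, :] - pos_um[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    crowded = np.min(d2, axis=1) < min_separation_um**2
    for cand, c in zip(candidates, crowded):
        if c and cand["included"]:
            cand["included"] = False
            cand["reason"] = "crowded"
    return candidates


def _gauss(x: np.ndarray, amp: float, mu: float, sigma: float, offset: float):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + offset


def _fit_profile(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Gaussian fit of a 1D profile; returns (fwhm, r2) or (nan, 0)."""
    y = np.asarray(y, dtype=float)
    if len(y) < 5 or np.ptp(y) <= 0:
        return np.nan, 0.0
    offset0 = float(np.min(y))
    amp0 = float(np.max(y) - offset0)
    mu0 = float(x[np.argmax(y)])
    above = y - offset0 > amp0 / 2
    sigma0 = max((np.sum(above) * (x[1] - x[0])) / SIGMA_TO_FWHM, (x[1] - x[0]) / 4)
    try:
        with warnings.catch_warnings():
            # noiseless phantoms fit exactly; the covariance warning is moot
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _gauss, x, y, p0=(amp0, mu0, sigma0, offset0), maxfev=5000
            )
    except RuntimeError:
        return np.nan, 0.0
    resid = y - _gauss(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return abs(popt[2]) * SIGMA_TO_FWHM, r2


def _subvolume(v: np.ndarray, center: tuple[int, int, int], half: tuple[int, int, int]):
    sl = tuple(
        slice(max(0, c - h), min(s, c + h + 1))
        for c, h, s in zip(center, half, v.shape)
    )
    return v[sl], tuple(s.start for s in sl)


def _refine_centroid(sub: np.ndarray) -> np.ndarray:
    w = np.clip(sub - np.median(sub), 0, None)
    total = w.sum()
    if total <= 0:
        return (np.array(sub.shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(s) for s in sub.shape], indexing="ij")
    return np.array([float((g * w).sum() / total) for g in grids])


def measure_fwhm(
    subvolume: np.ndarray, voxel_size_um: tuple[float, float, float]
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """FWHM along x, y, z from Gaussian fits of axis profiles through the
    sub-voxel centroid of a background-subtracted bead sub-volume.

    Returns ``((fwhm_x, fwhm_y, fwhm_z), (r2_x, r2_y, r2_z))`` in um.
    """
    sub = np.asarray(subvolume, dtype=float)
    centroid = _refine_centroid(sub)
    fwhms, r2s = [], []
    # axes in (z, y, x) voxel order; report x, y, z
    for axis in (2, 1, 0):
        coords = [
            np.full(sub.shape[axis], c) for c in centroid
        ]
        coords[axis] = np.arange(sub.shape[axis], dtype=float)
        prof = ndimage.map_coordinates(sub, np.stack(coords), order=1)
        x = np.arange(sub.shape[axis]) * voxel_size_um[axis]
        f, r2 = _fit_profile(x, prof)
        fwhms.append(f)
        r2s.append(r2)
    return tuple(fwhms), tuple(r2s)


def bead_sectioning(
    subvolume: np.ndarray, voxel_size_um: tuple[float, float, float]
) -> float:
    """FWHM of the axial profile of the laterally integrated bead signal.

    Raises if the profile has no usable peak (non-unimodal / flat)."""
    sub = np.asarray(subvolume, dtype=float)
    profile = sub.sum(axis=(1, 2))
    profile = profile - np.min(profile)
    z = np.arange(len(profile)) * voxel_size_um[0]
    fwhm, r2 = _fit_profile(z, profile)
    if not np.isfinite(fwhm) or r2 < 0.5:
        raise ValueError("axial profile is not a usable single peak")
    return fwhm


def measure_bead(
    volume: LabVolume,
    peak_index: tuple[int, int, int],
    fit_half_um: float = 2.0,
    sectioning_half_um: float = 4.0,
    r2_threshold: float = 0.9,
    border_fwhm: float = 1.0,
) -> BeadRecord:
    """Full per-bead measurement: FWHM fits plus sectioning strength.

    Inclusion requires fit r^2 >= threshold on every axis and a centroid at
    least one FWHM from the volume border.
    """
    v = volume.voxels
    sizes = volume.voxel_size_um
    half = tuple(max(2, int(round(fit_half_um / s))) for s in sizes)
    sub, origin = _subvolume(v, peak_index, half)
    background = float(np.median(sub))
    sub = sub - background
    centroid = _refine_centroid(sub) + np.array(origin)
    centroid_um = tuple(float(c * s) for c, s in zip(centroid, sizes))

    (fx, fy, fz), r2s = measure_fwhm(sub, sizes)
    record = BeadRecord(
        centroid_um=centroid_um, fwhm_x=fx, fwhm_y=fy, fwhm_z=fz, fit_r2=r2s
    )
    if not all(np.isfinite([fx, fy, fz])) or min(r2s) < r2_threshold:
        record.included = False
        record.exclusion_reason = "poor_fit"
        return record

    extent = (np.array(v.shape) - 1) * np.array(sizes)
    margins = np.minimum(centroid_um, extent - np.array(centroid_um))
    if margins[0] < border_fwhm * fz or min(margins[1:]) < border_fwhm * max(fx, fy):
        record.included = False
        record.exclusion_reason = "border"
        return record

    half_s = tuple(
        max(2, int(round((sectioning_half_um if ax == 0 else sectioning_half_um) / s)))
        for ax, s in enumerate(sizes)
    )
    sub_s, _ = _subvolume(v, peak_index, half_s)
    try:
        record.sectioning_fwhm = bead_sectioning(
            sub_s - float(np.median(sub_s)), sizes
        )
    except ValueError:
        record.sectioning_fwhm = np.nan
    return record


def measure_volume(
    volume: LabVolume,
    min_separation_um: float = 3.0,
    snr_threshold: float = 8.0,
    **kwargs,
) -> list[BeadRecord]:
    """Detect and measure every bead in a volume."""
    records = []
    for cand in detect_beads(volume, min_separation_um, snr_threshold):
        if not cand["included"]:
            records.append(
                BeadRecord(
                    centroid_um=cand["position_um"],
                    included=False,
                    exclusion_reason=cand["reason"],
                )
            )
            continue
        records.append(measure_bead(volume, cand["index"], **kwargs))
    return records


# ---------------------------------------------------------------------------
# sheet sectioning


def _column_gaussian_fwhm(columns: np.ndarray, dz: float) -> np.ndarray:
    """Vectorized Gaussian fit (log-parabola, Caruana) along axis 0.

    Exact for noiseless Gaussian columns; columns without a usable peak
    come back NaN.
    """
    nz, ncol = columns.shape
    z = np.arange(nz)[:, None] * dz
    peak = columns.max(axis=0)
    floor = np.minimum(columns.min(axis=0), 0)
    y = columns - floor
    peak_rel = y.max(axis=0)
    ok = peak_rel > 0
    fwhm = np.full(ncol, np.nan)

    # weight samples above 10% of the peak; log of a Gaussian is a parabola
    with np.errstate(divide="ignore", invalid="ignore"):
        mask = y > 0.1 * peak_rel
        w = np.where(mask, y, 0.0)
        logy = np.where(mask, np.log(np.where(y > 0, y, 1.0)), 0.0)
    # weighted LSQ of logy ~ a + b z + c z^2 per column
    ones = np.ones((nz, 1))
    design = [ones * np.ones((1, ncol)), z * np.ones((1, ncol)),
              z**2 * np.ones((1, ncol))]
    for j in np.nonzero(ok & (mask.sum(axis=0) >= 3))[0]:
        a = np.stack([d[:, j] for d in design], axis=1)
        wj = w[:, j]
        try:
            coef, *_ = np.linalg.lstsq(a * wj[:, None], logy[:, j] * wj, rcond=None)
        except np.linalg.LinAlgError:
            continue
        c = coef[2]
        if c < 0:
            sigma = math.sqrt(-1.0 / (2.0 * c))
            fwhm[j] = sigma * SIGMA_TO_FWHM
    return fwhm


def sheet_sectioning(
    sheet_volume: LabVolume, stride: int = 1
) -> tuple[np.ndarray, list[BeadSummary]]:
    """Per-(x, y) axial FWHM map of a thin-sheet volume plus its summary.

    Each lateral position is fit independently about its own axial peak, so
    a tilted sheet yields the same map as a flat one.  Columns without a
    peak are NaN-masked.
    """
    v = sheet_volume.voxels[:, ::stride, ::stride]
    nz = v.shape[0]
    cols = v.reshape(nz, -1)
    fwhm = _column_gaussian_fwhm(cols, sheet_volume.voxel_size_um[0])
    fwhm_map = fwhm.reshape(v.shape[1], v.shape[2])
    valid = fwhm_map[np.isfinite(fwhm_map)]
    summary = [_summary_from_values("sheet_sectioning", valid)] if valid.size else []
    return fwhm_map, summary


# ---------------------------------------------------------------------------
# summary statistics


def _median_ci95(values: np.ndarray) -> tuple[float, float]:
    """Distribution-free CI on the median from binomial order statistics."""
    x = np.sort(values)
    n = len(x)
    if n < 6:
        return float(x[0]), float(x[-1])
    lo = int(stats.binom.ppf(0.025, n, 0.5))
    hi = int(stats.binom.ppf(0.975, n, 0.5))
    return float(x[max(lo - 1, 0)]), float(x[min(hi, n - 1)])


def _summary_from_values(metric: str, values: np.ndarray) -> BeadSummary:
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return BeadSummary(
        metric=metric,
        n=len(values),
        median=float(q50),
        iqr=float(q75 - q25),
        ci95=_median_ci95(values),
    )


def summarize(records: list[BeadRecord]) -> list[BeadSummary]:
    """Median/IQR/95%-CI summaries over included bead records."""
    included = [r for r in records if r.included]
    if not included:
        raise ValueError("no included bead records to summarize")
    out = []
    for metric in ("fwhm_x", "fwhm_y", "fwhm_z", "sectioning_fwhm"):
        vals = np.array([getattr(r, metric) for r in included], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out.append(_summary_from_values(metric, vals))
    return out


def percent_change(median_a: float, median_b: float) -> float:
    """Percent change of b relative to a: 100 (b/a - 1)."""
    if median_a <= 0 or median_b <= 0:
        raise ValueError("medians must be positive")
    return 100.0 * (median_b / median_a - 1.0)


# ---------------------------------------------------------------------------
# relative collection efficiency (bead photometry)


def airy_encircled_energy(x: float | np.ndarray) -> np.ndarray:
    """Fraction of Airy-pattern energy within reduced radius
    x = 2 pi NA r / lambda: 1 - J0(x)^2 - J1(x)^2."""
    x = np.asarray(x, dtype=float)
    return 1.0 - special.j0(x) ** 2 - special.j1(x) ** 2


def airy_radius(
    fraction: float, wavelength_um: float, na: float
) -> float:
    """Radius (um) enclosing the given energy fraction of an Airy spot."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    x = optimize.brentq(lambda t: airy_encircled_energy(t) - fraction, 1e-6, 1e4)
    return x * wavelength_um / (2.0 * math.pi * na)


def relative_efficiency(
    epi_image: np.ndarray,
    dopm_image: np.ndarray,
    bead_center: tuple[int, int],
    wavelength_um: float = 0.52,
    na: float = 1.2,
    pixel_size_um: float = 0.1,
    energy_fraction: float = 0.99,
) -> RelativeEfficiencyMeasurement:
    """Background-corrected signal ratio between a matched epi/dOPM image
    pair of one isolated bead.

    The square ROI side is set from the Airy encircled-energy radius at the
    requested fraction; background comes from an adjacent equal ROI.
    """
    epi = np.asarray(epi_image, dtype=float)
    dopm = np.asarray(dopm_image, dtype=float)
    if epi.shape != dopm.shape:
        raise ValueError("image pair must share a shape")
    r_um = airy_radius(energy_fraction, wavelength_um, na)
    half = max(1, int(math.ceil(r_um / pixel_size_um)))
    r0, c0 = bead_center

    def roi_sum(img: np.ndarray, r: int, c: int) -> float:
        if r - half < 0 or c - half < 0 or r + half >= img.shape[0] or c + half >= img.shape[1]:
            raise ValueError("ROI extends beyond the image")
        return float(img[r - half : r + half + 1, c - half : c + half + 1].sum())

    side = 2 * half + 1
    # adjacent background ROI: shifted one full ROI along columns
    c_bg = c0 + side if c0 + side + half < epi.shape[1] else c0 - side
    s_epi, b_epi = roi_sum(epi, r0, c0), roi_sum(epi, r0, c_bg)
    s_dopm, b_dopm = roi_sum(dopm, r0, c0), roi_sum(dopm, r0, c_bg)
    if s_epi <= b_epi:
        raise ValueError("epi signal does not exceed background; eta undefined")
    return RelativeEfficiencyMeasurement(
        s_dopm=s_dopm, b_dopm=b_dopm, s_epi=s_epi, b_epi=b_epi, roi_half_px=half
    )


# ---------------------------------------------------------------------------
# photobleaching


def photobleach_stats(
    timeseries_rois: np.ndarray, n_edge_frames: int = 3
) -> dict:
    """Percent signal drop over a time-lapse, per ROI and summarized.

    The drop is 100 (1 - I_end / I_start) with start/end estimated as means
    of the first/last ``n_edge_frames`` frames; the summary is the median
    and IQR across ROIs.
    """
    series = np.atleast_2d(np.asarray(timeseries_rois, dtype=float))
    if series.shape[1] < 2:
        raise ValueError("need at least two timepoints")
    k = max(1, min(n_edge_frames, series.shape[1] // 2))
    start = series[:, :k].mean(axis=1)
    end = series[:, -k:].mean(axis=1)
    drops = 100.0 * (1.0 - end / start)
    q25, q50, q75 = np.percentile(drops, [25, 50, 75])
    return {
        "per_roi_percent_drop": drops,
        "median_percent_drop": float(q50),
        "iqr_percent_drop": float(q75 - q25),
    }
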