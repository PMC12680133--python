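import math

import numpy as np
import pytest
from scipy import integrate

from dopm.metrology import (
    SIGMA_TO_FWHM,
    BeadRecord,
    airy_encircled_energy,
    airy_radius,
    bead_sectioning,
    detect_beads,
    measure_fwhm,
    measure_volume,
    percent_change,
    photobleach_stats,
    relative_efficiency,
    sheet_sectioning,
    summarize,
)
from dopm.synthetic import PhantomSpec, make_bead_phantom, make_sheet_phantom
from dopm.volume import LabVolume


def _gaussian_bead(sigma_um, voxel_um=0.05, half_um=1.2, peak=1000.0, offset=0.0):
    n = int(round(half_um / voxel_um))
    ax = (np.arange(2 * n + 1) - n) * voxel_um
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    sz, sy, sx = sigma_um if isinstance(sigma_um, tuple) else (sigma_um,) * 3
    g = peak * np.exp(-0.5 * ((z / sz) ** 2 + (y / sy) ** 2 + (x / sx) ** 2))
    return g + offset


class TestDetectBeads:
    def test_known_phantom_positions(self):
        spec = PhantomSpec(
            shape_um=(20.0, 20.0, 20.0),
            voxel_size_um=(0.2, 0.2, 0.2),
            n_beads=20,
            bead_fwhm_um=(0.6, 0.6, 1.2),
            min_separation_um=4.0,
            border_um=2.5,
            peak_photons=5000.0,
            seed=7,
        )
        vol, truth = make_bead_phantom(spec)
        candidates = [c for c in detect_beads(vol, min_separation_um=3.0)
                      if c["included"]]
        assert len(candidates) == 20
        found = np.array([c["position_um"] for c in candidates])
        truth_pos = truth[["z_um", "y_um", "x_um"]].to_numpy()
        for p in truth_pos:
            nearest = np.min(np.linalg.norm(found - p, axis=1))
            assert nearest <= 0.2 * math.sqrt(3) + 1e-9  # within one voxel

    def test_uniform_background_no_detections(self, rng):
        vol = LabVolume(rng.poisson(50, (40, 40, 40)).astype(float), (0.2,) * 3)
        cands = detect_beads(vol)
        assert cands == []

    def test_crowded_pair_both_excluded(self):
        v = np.zeros((40, 40, 40))
        v[20, 20, 20] = 1000.0
        v[20, 20, 26] = 900.0  # 1.2 um away at 0.2 um voxels
        vol = LabVolume(v, (0.2,) * 3)
        cands = detect_beads(vol, min_separation_um=3.0)
        assert len(cands) == 2
        assert all(not c["included"] and c["reason"] == "crowded" for c in cands)


class TestMeasureFwhm:
    def test_isotropic_gaussian(self):
        sigma = 0.124
        sub = _gaussian_bead(sigma)
        (fx, fy, fz), r2 = measure_fwhm(sub, (0.05, 0.05, 0.05))
        expected = sigma * SIGMA_TO_FWHM  # 0.292 um
        for f in (fx, fy, fz):
            assert f == pytest.approx(expected, rel=0.02)
        assert min(r2) > 0.99

    def test_lateral_symmetry(self):
        sub = _gaussian_bead(0.15)
        (fx, fy, _), _ = measure_fwhm(sub, (0.05, 0.05, 0.05))
        assert fx == pytest.approx(fy, rel=0.01)

    def test_anisotropy_ratio(self):
        sub = _gaussian_bead((0.35, 0.125, 0.125), voxel_um=0.05, half_um=2.0)
        (fx, _, fz), _ = measure_fwhm(sub, (0.05, 0.05, 0.05))
        assert fz / fx == pytest.approx(2.8, rel=0.05)

    @pytest.mark.parametrize("peak", [100.0, 1000.0])  # SNR ~10 and ~30
    def test_unbiased_across_snr(self, rng, peak):
        sigma = 0.2  # 4.7 voxels FWHM at 0.1 um sampling
        clean = _gaussian_bead(sigma, voxel_um=0.1, half_um=1.5, peak=peak,
                               offset=10.0)
        measured = []
        for _ in range(20):
            noisy = rng.poisson(clean).astype(float) - 10.0
            fwhms, _ = measure_fwhm(noisy, (0.1, 0.1, 0.1))
            measured.extend(fwhms)
        # unbiased: the mean over noise realizations matches the truth
        assert np.mean(measured) == pytest.approx(sigma * SIGMA_TO_FWHM, rel=0.02)


class TestBeadSectioning:
    def test_separable_gaussian_equals_axial(self):
        sub = _gaussian_bead((0.35, 0.15, 0.15), voxel_um=0.05, half_um=2.0)
        fwhm = bead_sectioning(sub, (0.05, 0.05, 0.05))
        assert fwhm == pytest.approx(0.35 * SIGMA_TO_FWHM, rel=0.02)

    def test_defocus_spread_exceeds_axial(self):
        # per-plane energy constant over a wider axial range than the
        # in-focus axial FWHM: lateral sigma grows with |z|, energy fixed
        n = 40
        z_um = (np.arange(2 * n + 1) - n) * 0.05
        ax = (np.arange(81) - 40) * 0.05
        y, x = np.meshgrid(ax, ax, indexing="ij")
        axial_sigma = 0.2
        vol = np.empty((2 * n + 1, 81, 81))
        for k, z in enumerate(z_um):
            lateral_sigma = 0.1 * (1 + (z / 0.3) ** 2) ** 0.5
            plane_energy = math.exp(-0.5 * (z / (3 * axial_sigma)) ** 2)
            psf = np.exp(-0.5 * ((y / lateral_sigma) ** 2 + (x / lateral_sigma) ** 2))
            vol[k] = plane_energy * psf / psf.sum()
        sectioning = bead_sectioning(vol, (0.05, 0.05, 0.05))
        # axial FWHM of the central-voxel profile is much narrower
        center = vol[:, 40, 40]
        from dopm.metrology import _fit_profile

        axial_fwhm, _ = _fit_profile(z_um, center)
        assert sectioning > axial_fwhm

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError):
            bead_sectioning(np.ones((20, 10, 10)), (0.1, 0.1, 0.1))


class TestSheetSectioning:
    def test_gaussian_sheet_median(self):
        sheet = make_sheet_phantom(3.0, 0.0, 0.0)
        fwhm_map, summaries = sheet_sectioning(sheet, stride=4)
        assert summaries[0].median == pytest.approx(3.0, rel=0.02)

    def test_tilted_sheet_unchanged(self):
        flat = make_sheet_phantom(3.0, 0.0, 0.0, shape_um=(30.0, 10.0, 10.0))
        tilted = make_sheet_phantom(3.0, 10.0, 0.0, shape_um=(30.0, 10.0, 10.0))
        _, s_flat = sheet_sectioning(flat, stride=4)
        _, s_tilt = sheet_sectioning(tilted, stride=4)
        assert s_tilt[0].median == pytest.approx(s_flat[0].median, rel=0.01)

    def test_thin_sheet_sampling_floor(self):
        sheet = make_sheet_phantom(
            0.3, 0.0, 0.0, voxel_size_um=(0.25, 0.5, 0.5)
        )
        fwhm_map, summaries = sheet_sectioning(sheet, stride=4)
        # FWHM cannot drop meaningfully below the voxel sampling
        assert summaries[0].median >= 0.25

    def test_no_peak_columns_masked(self):
        vol = LabVolume(np.zeros((20, 8, 8)), (0.25, 0.5, 0.5))
        fwhm_map, summaries = sheet_sectioning(vol)
        assert np.all(np.isnan(fwhm_map))
        assert summaries == []


class TestSummarize:
    def _records(self, values):
        return [
            BeadRecord(centroid_um=(0, 0, 0), fwhm_x=v, fwhm_y=v, fwhm_z=v,
                       sectioning_fwhm=v, fit_r2=(1, 1, 1))
            for v in values
        ]

    def test_matches_sort_oracle(self, rng):
        values = rng.lognormal(0.0, 0.3, 51)
        summary = summarize(self._records(values))[0]
        ordered = np.sort(values)
        assert summary.median == pytest.approx(float(np.median(ordered)))
        q75, q25 = np.percentile(ordered, [75, 25])
        assert summary.iqr == pytest.approx(float(q75 - q25))
        assert summary.ci95[0] <= summary.median <= summary.ci95[1]

    def test_permutation_invariance(self, rng):
        values = rng.uniform(0.2, 0.5, 30)
        a = summarize(self._records(values))[0]
        b = summarize(self._records(rng.permutation(values)))[0]
        assert a.median == b.median and a.iqr == b.iqr and a.ci95 == b.ci95

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_ci_coverage_near_95_percent(self, rng):
        from dopm.metrology import _median_ci95

        true_median = 1.0
        n_sims, n = 1000, 25
        covered = 0
        for _ in range(n_sims):
            sample = rng.lognormal(0.0, 0.4, n)  # median exp(0) = 1
            lo, hi = _median_ci95(sample)
            covered += lo <= true_median <= hi
        assert 0.92 <= covered / n_sims <= 0.99


class TestPercentChange:
    def test_table_medians(self):
        assert round(percent_change(0.293, 0.301), 1) == 2.7

    def test_identity(self):
        assert percent_change(0.4, 0.4) == 0.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 0.3)


class TestAiryPhotometry:
    def test_encircled_energy_against_quadrature(self):
        # oracle: numerically integrate the Airy intensity (2 J1(x)/x)^2
        from scipy.special import j1

        for frac in (0.8, 0.9, 0.99):
            x_max = airy_radius(frac, 1.0, 1.0) * 2 * math.pi  # reduced units
            val, _ = integrate.quad(
                lambda x: (2 * j1(x) / x) ** 2 * x / 2, 0, x_max, limit=500
            )
            assert val == pytest.approx(frac, abs=1e-3)

    def test_constructed_ratio(self):
        ax = (np.arange(160) - 60) * 0.2
        y, x = np.meshgrid(ax, ax, indexing="ij")
        spot = np.exp(-0.5 * ((y / 0.3) ** 2 + (x / 0.3) ** 2))
        epi = 1000 * spot + 50.0
        dopm = 230 * spot + 50.0
        m = relative_efficiency(epi, dopm, (60, 60), pixel_size_um=0.2)
        assert m.eta == pytest.approx(0.23, rel=0.02)

    def test_identical_images(self):
        ax = (np.arange(160) - 60) * 0.2
        y, x = np.meshgrid(ax, ax, indexing="ij")
        img = 500 * np.exp(-0.5 * ((y / 0.3) ** 2 + (x / 0.3) ** 2)) + 10
        m = relative_efficiency(img, img.copy(), (60, 60), pixel_size_um=0.2)
        assert m.eta == pytest.approx(1.0, rel=1e-6)

    def test_offset_invariance(self):
        ax = (np.arange(160) - 60) * 0.2
        y, x = np.meshgrid(ax, ax, indexing="ij")
        spot = np.exp(-0.5 * ((y / 0.3) ** 2 + (x / 0.3) ** 2))
        epi, dopm = 1000 * spot + 20, 400 * spot + 20
        m0 = relative_efficiency(epi, dopm, (60, 60), pixel_size_um=0.2)
        m1 = relative_efficiency(epi + 75, dopm + 75, (60, 60), pixel_size_um=0.2)
        assert m1.eta == pytest.approx(m0.eta, rel=1e-9)

    def test_signal_below_background_rejected(self):
        flat = np.full((160, 160), 10.0)
        with pytest.raises(ValueError):
            relative_efficiency(flat, flat, (60, 60), pixel_size_um=0.2)


class TestPhotobleachStats:
    def test_exponential_half_drop(self):
        t = np.arange(100)
        series = np.exp(-math.log(2) / 99 * t)[None, :] * 1000
        stats = photobleach_stats(series, n_edge_frames=1)
        assert stats["median_percent_drop"] == pytest.approx(50.0, abs=1e-9)

    def test_constant_series(self):
        stats = photobleach_stats(np.full((5, 20), 123.0))
        assert stats["median_percent_drop"] == 0.0
        assert stats["iqr_percent_drop"] == 0.0

    def test_noisy_ensemble_matches_analytic(self, rng):
        from dopm.synthetic import make_bleach_series

        n_t, dt = 60, 60.0
        duration = (n_t - 1) * dt
        target_drop = 0.66
        k = -math.log(1 - target_drop) / duration
        series = make_bleach_series(
            np.full(40, k), n_t, dt, noise_rms=5.0, seed=4, initial_intensity=1000.0
        )
        stats = photobleach_stats(series, n_edge_frames=1)
        assert stats["median_percent_drop"] == pytest.approx(66.0, abs=2.0)

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError):
            photobleach_stats(np.ones((3, 1)))
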