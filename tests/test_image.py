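import math

import numpy as np
import pytest
from scipy import ndimage

from petkin import FrameSchedule, InputFunction
from petkin.image import (
    DynamicImage,
    PvcCalibration,
    VoxelMask,
    calibrate_pvc,
    isocontour_voi,
    mask_tac,
    pvc_correct_idif,
    shell_mask,
    sphere_voi,
)
from petkin.synthetic import SyntheticTruth, PhantomGeometry, make_phantom
from petkin.tac import TimeActivityCurve


def _image(data3d_or_4d, voxel=1.0, n_frames=None):
    data = np.asarray(data3d_or_4d, float)
    if data.ndim == 3:
        nf = n_frames or 4
        data = np.repeat(data[..., None], nf, axis=3)
    sched = FrameSchedule.from_durations([900.0] * data.shape[3])
    vs = (voxel,) * 3 if np.isscalar(voxel) else tuple(voxel)
    return DynamicImage(data=data, voxel_size=vs, schedule=sched)


class TestIsocontour:
    def test_uniform_sphere_recovered_exactly(self):
        vol = np.zeros((32, 32, 32))
        zz = np.indices(vol.shape)
        r2 = sum((z - 15.5) ** 2 for z in zz)
        sphere = r2 <= 8.0**2
        vol[sphere] = 100.0
        img = _image(vol)
        mask = isocontour_voi(img, seed_point=(16, 16, 16), window_min=(0.0, 60.0))
        assert np.array_equal(mask.data, sphere)

    def test_shell_below_threshold_excluded(self):
        vol = np.zeros((24, 24, 24))
        zz = np.indices(vol.shape)
        r2 = sum((z - 11.5) ** 2 for z in zz)
        core = r2 <= 5.0**2
        shell = (r2 > 5.0**2) & (r2 <= 9.0**2)
        vol[core] = 100.0
        vol[shell] = 30.0  # below the 40% cut
        img = _image(vol)
        mask = isocontour_voi(img, seed_point=(12, 12, 12), window_min=(0.0, 60.0))
        assert np.array_equal(mask.data, core)

    def test_gaussian_blob_radius_analytic(self):
        """Threshold at 40% of a Gaussian peak: r = sigma*sqrt(2 ln(1/0.4))."""
        sigma = 4.0
        vol = np.zeros((48, 48, 48))
        zz = np.indices(vol.shape)
        r2 = sum((z - 23.5) ** 2 for z in zz)
        vol = 100.0 * np.exp(-r2 / (2.0 * sigma**2))
        img = _image(vol)
        mask = isocontour_voi(img, seed_point=(24, 24, 24), window_min=(0.0, 60.0))
        r_analytic = sigma * math.sqrt(2.0 * math.log(1.0 / 0.4))
        v_analytic = 4.0 / 3.0 * math.pi * r_analytic**3
        assert mask.n_voxels == pytest.approx(v_analytic, rel=0.10)

    def test_invariant_to_global_scaling(self):
        rng = np.random.default_rng(2)
        vol = rng.uniform(0.0, 1.0, (16, 16, 16))
        vol[6:10, 6:10, 6:10] += 10.0
        m1 = isocontour_voi(_image(vol), (8, 8, 8), window_min=(0.0, 60.0))
        m2 = isocontour_voi(_image(vol * 7.3), (8, 8, 8), window_min=(0.0, 60.0))
        assert np.array_equal(m1.data, m2.data)

    def test_cold_seed_rejected(self):
        vol = np.zeros((8, 8, 8))
        vol[4, 4, 4] = 10.0
        with pytest.raises(ValueError):
            isocontour_voi(_image(vol), (0, 0, 0), window_min=(0.0, 60.0))


class TestSphereVoi:
    def test_one_ml_voxel_count(self):
        img = _image(np.zeros((24, 24, 24)), voxel=1.0)
        mask = sphere_voi(img, center_mm=(12.0, 12.0, 12.0), volume_ml=1.0)
        # digital sphere of r ~ 6.2 mm holds ~1000 one-microlitre voxels
        assert mask.n_voxels == pytest.approx(1000.0, rel=0.05)

    def test_degenerate_volume_single_voxel(self):
        img = _image(np.zeros((10, 10, 10)), voxel=1.0)
        mask = sphere_voi(img, center_mm=(5.0, 5.0, 5.0), volume_ml=1e-9)
        assert mask.n_voxels == 1

    def test_doubling_voxel_volume_halves_count(self):
        img1 = _image(np.zeros((40, 40, 40)), voxel=1.0)
        n1 = sphere_voi(img1, (20.0, 20.0, 20.0), 1.0).n_voxels
        img2 = _image(np.zeros((40, 40, 20)), voxel=(1.0, 1.0, 2.0))
        n2 = sphere_voi(img2, (20.0, 20.0, 20.0), 1.0).n_voxels
        assert n2 == pytest.approx(n1 / 2.0, rel=0.05)

    def test_out_of_bounds_rejected(self):
        img = _image(np.zeros((10, 10, 10)), voxel=1.0)
        with pytest.raises(ValueError, match="outside"):
            sphere_voi(img, (2.0, 5.0, 5.0), 1.0)


class TestMaskTac:
    def test_uniform_image_either_statistic(self):
        img = _image(np.full((6, 6, 6), 7.0))
        mask = VoxelMask(data=np.ones((6, 6, 6), bool))
        for stat in ("mean", "median"):
            assert np.allclose(mask_tac(img, mask, stat).values, 7.0)

    def test_order_statistics(self):
        data = np.zeros((3, 1, 1, 2))
        data[:, 0, 0, 0] = [1.0, 2.0, 100.0]
        data[:, 0, 0, 1] = [1.0, 2.0, 100.0]
        sched = FrameSchedule.from_durations([60.0, 60.0])
        img = DynamicImage(data=data, voxel_size=(1, 1, 1), schedule=sched)
        mask = VoxelMask(data=np.ones((3, 1, 1), bool))
        assert mask_tac(img, mask, "median").values[0] == 2.0
        assert mask_tac(img, mask, "mean").values[0] == pytest.approx(103.0 / 3.0)

    def test_median_robust_to_minority_outliers(self):
        rng = np.random.default_rng(1)
        base = np.full((9, 9, 1), 50.0)
        img_clean = _image(base, n_frames=2)
        corrupted = base.copy()
        idx = rng.choice(81, size=30, replace=False)  # <50% of voxels
        corrupted.reshape(-1)[idx] += rng.uniform(100.0, 1000.0, 30)
        img_bad = _image(corrupted, n_frames=2)
        mask = VoxelMask(data=np.ones((9, 9, 1), bool))
        med_clean = mask_tac(img_clean, mask, "median").values
        med_bad = mask_tac(img_bad, mask, "median").values
        assert np.allclose(med_clean, med_bad)

    def test_full_mask_mean_equals_global_mean(self):
        rng = np.random.default_rng(6)
        img = _image(rng.uniform(0, 10, (5, 6, 7)), n_frames=3)
        mask = VoxelMask(data=np.ones((5, 6, 7), bool))
        out = mask_tac(img, mask, "mean").values
        assert np.allclose(out, img.data.mean(axis=(0, 1, 2)))

    def test_grid_mismatch_rejected(self):
        img = _image(np.zeros((4, 4, 4)))
        mask = VoxelMask(data=np.ones((5, 5, 5), bool))
        with pytest.raises(ValueError, match="mismatch"):
            mask_tac(img, mask)


class TestPvcCorrection:
    def _tacs(self):
        sched = FrameSchedule.from_durations([60.0] * 5)
        raw = TimeActivityCurve(schedule=sched,
                                values=np.array([10.0, 40.0, 30.0, 20.0, 15.0]))
        bg = TimeActivityCurve(schedule=sched,
                               values=np.array([2.0, 4.0, 8.0, 10.0, 11.0]))
        return raw, bg

    def test_identity_when_rc_one_s_zero(self):
        raw, bg = self._tacs()
        cal = PvcCalibration(diameters=np.array([8.0, 9.0]),
                             rc=np.array([1.0, 1.0]), s=np.array([0.0, 0.0]))
        out = pvc_correct_idif(raw, bg, cal, 8.5)
        assert np.allclose(out.value, raw.values)
        assert out.provenance == "image_derived"

    def test_exact_inversion_of_forward_contamination(self):
        raw, bg = self._tacs()
        rc, s = 0.6, 0.1
        true = raw.values
        measured = TimeActivityCurve(schedule=raw.schedule,
                                     values=rc * true + s * bg.values)
        cal = PvcCalibration(diameters=np.array([8.0, 9.0]),
                             rc=np.array([rc, rc]), s=np.array([s, s]))
        out = pvc_correct_idif(measured, bg, cal, 9.0)
        assert np.allclose(out.value, true)

    def test_zero_background_rc_half_doubles(self):
        raw, bg = self._tacs()
        zero_bg = TimeActivityCurve(schedule=raw.schedule, values=np.zeros(5))
        cal = PvcCalibration(diameters=np.array([8.0, 9.0]),
                             rc=np.array([0.5, 0.5]), s=np.array([0.2, 0.2]))
        out = pvc_correct_idif(raw, zero_bg, cal, 8.0)
        assert np.allclose(out.value, 2.0 * raw.values)

    def test_out_of_range_diameter_rejected(self):
        raw, bg = self._tacs()
        cal = PvcCalibration(diameters=np.array([8.0, 9.0]),
                             rc=np.array([0.6, 0.7]), s=np.array([0.1, 0.1]))
        with pytest.raises(ValueError, match="outside"):
            pvc_correct_idif(raw, bg, cal, 12.0)


def _calibration_inputs(psf_fwhm, diameters=(8.0, 9.0), voxel=2.0, zero_bg=False):
    """Single-vessel phantoms with distinct vessel/background time courses."""
    n = int(96 / voxel)
    truth = SyntheticTruth(
        geometry=PhantomGeometry(psf_fwhm_mm=psf_fwhm,
                                 vessel_diameters_mm=diameters,
                                 voxel_size_mm=(voxel,) * 3,
                                 shape=(n, n, max(int(24 / voxel), 8)))
    )
    sched = FrameSchedule.from_durations([300.0] * 6)
    t = np.arange(0.0, sched.total_duration + 1.0)
    wb = InputFunction(time=t, value=5000.0 * np.exp(-t / 900.0))
    bg_values = np.zeros(6) if zero_bg else 500.0 + 100.0 * np.arange(6.0)
    bg = TimeActivityCurve(schedule=sched, values=bg_values, region_label="bg")
    entries = []
    for d in diameters:
        ph = make_phantom(truth, wb, bg, schedule=sched, diameters=(d,))
        entries.append((d, ph.image, ph.vessel_masks[d], ph.true_vessel_values))
    return entries


class TestCalibratePvc:
    def test_delta_psf_gives_near_perfect_recovery(self):
        # 1 mm voxels so the median in-mask voxel is fully interior
        cal = calibrate_pvc(_calibration_inputs(psf_fwhm=0.0, voxel=1.0))
        assert np.all(cal.rc > 0.99)
        assert np.all(cal.s < 0.01)

    def test_rc_monotone_in_diameter(self):
        cal = calibrate_pvc(_calibration_inputs(psf_fwhm=4.0))
        assert cal.rc_at(9.0) >= cal.rc_at(8.0)
        assert np.all(cal.rc < 1.0)  # genuine partial-volume loss at 4 mm FWHM

    def test_blurred_cylinder_matches_quadrature_oracle(self):
        """Median in-mask recovery of a blurred unit cylinder equals the
        numerically integrated 2-D Gaussian-over-disk value per voxel."""
        fwhm, d, voxel = 4.0, 8.0, 2.0
        sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        entries = _calibration_inputs(psf_fwhm=fwhm, diameters=(d, 9.0),
                                      zero_bg=True)
        _, img, mask, truth_vals = entries[0]

        # oracle: fine-grid convolution integral evaluated at voxel centres
        r = d / 2.0
        h = 0.05
        u = np.arange(-r, r + h / 2, h)
        U, V = np.meshgrid(u, u, indexing="ij")
        in_disk = (U**2 + V**2) <= r**2
        centre = (img.data.shape[0] / 2.0) * voxel  # vessel centred in FOV
        rows = np.where(mask.data[:, :, 0])
        rcs = []
        for ix, iy in zip(*rows):
            x0 = (ix + 0.5) * voxel - centre
            y0 = (iy + 0.5) * voxel - centre
            g = np.exp(-((U - x0) ** 2 + (V - y0) ** 2) / (2.0 * sigma**2))
            rcs.append(g[in_disk].sum() * h * h / (2.0 * math.pi * sigma**2))
        rc_oracle = float(np.median(rcs))

        measured = mask_tac(img, mask, "median").values
        # pick a frame where background is negligible relative to vessel
        rc_measured = measured[0] / truth_vals[0]
        assert rc_measured == pytest.approx(rc_oracle, rel=0.05)

    def test_single_diameter_rejected(self):
        entries = _calibration_inputs(psf_fwhm=4.0)[:1]
        with pytest.raises(ValueError, match="diameters"):
            calibrate_pvc(entries)


def test_shell_mask_distances():
    data = np.zeros((21, 21, 5), bool)
    data[10, 10, :] = True
    vessel = VoxelMask(data=data, label="v")
    shell = shell_mask(vessel, (1.0, 1.0, 1.0), inner_mm=2.0, outer_mm=6.0)
    dist = ndimage.distance_transform_edt(~data)
    assert np.array_equal(shell.data, (dist > 2.0) & (dist <= 6.0))
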