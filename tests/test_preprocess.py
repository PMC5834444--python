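"""SUV conversion, resampling, smoothing and thresholding."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage

from petavid.preprocess import (
    GaussianKernelSpec,
    convert_to_suv,
    gaussian_smooth,
    preprocess,
    resample_isotropic,
    threshold_suv,
)
from petavid.volumes import InvalidMetadataError, ParameterError, PETScan, SUVVolume

from conftest import make_suv, sphere_mask


def make_scan(voxels, spacing=(4.0, 4.0, 4.0), weight_g=70000.0, dose_bq=3.7e8,
              elapsed_min=0.0, halflife_min=109.77):
    return PETScan(
        voxels=np.asarray(voxels, dtype=float), spacing=spacing, weight_g=weight_g,
        dose_bq=dose_bq, elapsed_min=elapsed_min, halflife_min=halflife_min,
    )


class TestConvertToSUV:
    def test_no_decay_at_zero_elapsed(self):
        scan = make_scan(np.full((3, 3, 3), 1000.0), weight_g=50000.0, dose_bq=2e8)
        suv = convert_to_suv(scan)
        assert np.allclose(suv.voxels, 1000.0 * 50000.0 / 2e8)

    def test_one_halflife_doubles_value(self):
        # C=5000, W=70 kg, D=370 MBq, t=T1/2 -> SUV = 2*5000*70000/3.7e8
        scan = make_scan(np.full((2, 2, 2), 5000.0), elapsed_min=109.77)
        suv = convert_to_suv(scan)
        assert np.allclose(suv.voxels, 2 * 5000.0 * 70000.0 / 3.7e8)
        assert np.allclose(suv.voxels, 1.8918918918918919, atol=1e-4)

    def test_zero_activity_gives_zero_suv(self):
        suv = convert_to_suv(make_scan(np.zeros((4, 4, 4)), elapsed_min=33.0))
        assert np.all(suv.voxels == 0.0)

    def test_grid_is_preserved(self):
        scan = make_scan(np.ones((3, 4, 5)), spacing=(2.0, 3.0, 4.0))
        suv = convert_to_suv(scan)
        assert suv.voxels.shape == (3, 4, 5)
        assert suv.spacing == (2.0, 3.0, 4.0)

    def test_linearity_in_activity_and_dose(self, rng):
        vox = rng.uniform(0, 1e4, size=(4, 4, 4))
        base = convert_to_suv(make_scan(vox)).voxels
        doubled_c = convert_to_suv(make_scan(2 * vox)).voxels
        doubled_d = convert_to_suv(make_scan(vox, dose_bq=2 * 3.7e8)).voxels
        assert np.allclose(doubled_c, 2 * base)
        assert np.allclose(doubled_d, base / 2)

    def test_one_halflife_later_exactly_doubles(self, rng):
        vox = rng.uniform(0, 1e4, size=(3, 3, 3))
        t = 47.0
        s1 = convert_to_suv(make_scan(vox, elapsed_min=t)).voxels
        s2 = convert_to_suv(make_scan(vox, elapsed_min=t + 109.77)).voxels
        assert np.allclose(s2, 2 * s1, rtol=1e-12)

    @pytest.mark.parametrize(
        "field,value",
        [("weight_g", 0.0), ("weight_g", -1.0), ("dose_bq", 0.0),
         ("halflife_min", 0.0), ("elapsed_min", -5.0)],
    )
    def test_invalid_metadata_rejected(self, field, value):
        kwargs = {field: value}
        with pytest.raises(InvalidMetadataError):
            make_scan(np.ones((2, 2, 2)), **kwargs)


class TestResampleIsotropic:
    def test_constant_volume_stays_constant(self):
        vol = SUVVolume(np.full((10, 12, 8), 4.2), (3.0, 4.0, 5.0))
        out = resample_isotropic(vol, 5.0)
        assert out.spacing == (5.0, 5.0, 5.0)
        assert np.allclose(out.voxels, 4.2, atol=1e-9)

    def test_identity_when_already_at_target(self, rng):
        vol = make_suv(rng.uniform(0, 8, size=(6, 6, 6)), spacing=5.0)
        out = resample_isotropic(vol, 5.0)
        assert np.array_equal(out.voxels, vol.voxels)

    def test_linear_field_reproduced_exactly(self):
        # SUV(x,y,z) = physical x + 2y + 3z: cubic interpolation is exact on
        # linear functions away from the boundary
        # the cubic-spline prefilter's boundary transient decays geometrically,
        # so "away from boundaries" means ~8 target voxels here
        spacing = (2.0, 3.0, 4.0)
        shape = (51, 43, 41)
        idx = np.indices(shape, dtype=float)
        phys = [idx[a] * spacing[a] for a in range(3)]
        vol = SUVVolume(phys[0] + 2 * phys[1] + 3 * phys[2], spacing)
        out = resample_isotropic(vol, 5.0)
        nidx = np.indices(out.voxels.shape, dtype=float) * 5.0
        expected = nidx[0] + 2 * nidx[1] + 3 * nidx[2]
        interior = (slice(8, -8),) * 3
        assert np.allclose(out.voxels[interior], expected[interior], atol=1e-6)

    def test_physical_extent_preserved_within_one_voxel(self):
        vol = SUVVolume(np.ones((40, 40, 20)), (2.0, 2.0, 6.0))
        out = resample_isotropic(vol, 5.0)
        for ax in range(3):
            old_extent = (vol.voxels.shape[ax] - 1) * vol.spacing[ax]
            new_extent = (out.voxels.shape[ax] - 1) * 5.0
            assert abs(old_extent - new_extent) <= 5.0

    def test_metadata_preserved_for_scans(self):
        scan = make_scan(np.ones((8, 8, 8)), spacing=(2.0, 2.0, 2.0))
        out = resample_isotropic(scan, 5.0)
        assert isinstance(out, PETScan)
        assert out.weight_g == scan.weight_g

    def test_rejects_bad_target(self):
        with pytest.raises(ParameterError):
            resample_isotropic(make_suv(np.ones((3, 3, 3))), 0.0)


class TestGaussianSmooth:
    def test_constant_field_unchanged(self):
        out = gaussian_smooth(make_suv(np.full((9, 9, 9), 2.5)))
        assert np.allclose(out.voxels, 2.5, atol=1e-9)

    def test_impulse_response_is_normalized_gaussian(self):
        vox = np.zeros((21, 21, 21))
        vox[10, 10, 10] = 1.0
        out = gaussian_smooth(make_suv(vox), GaussianKernelSpec(sigma_vox=1.0))
        assert abs(out.voxels.sum() - 1.0) < 1e-6
        # isotropy and monotone decay from the centre
        assert out.voxels[10, 10, 10] == out.voxels.max()
        assert np.isclose(out.voxels[11, 10, 10], out.voxels[10, 11, 10])
        # ratio of neighbour to centre equals exp(-1/(2 sigma^2)) for the
        # discrete kernel (separable, normalised)
        k1d = ndimage.gaussian_filter1d(
            np.eye(1, 21, 10).ravel(), 1.0, truncate=4.0
        )
        assert np.isclose(out.voxels[11, 10, 10] / out.voxels[10, 10, 10],
                          k1d[11] / k1d[10], rtol=1e-9)

    def test_noise_variance_reduced_by_sum_of_squared_weights(self, rng):
        # var(out) ~= var(in) * sum(k^2) for i.i.d. input noise
        impulse = np.zeros((17, 17, 17))
        impulse[8, 8, 8] = 1.0
        kernel = ndimage.gaussian_filter(impulse, 1.0, truncate=4.0)
        k2 = float((kernel**2).sum())
        noise = rng.normal(0, 1, size=(60, 60, 60))
        out = gaussian_smooth(
            SUVVolume(noise - noise.min(), (5.0,) * 3), GaussianKernelSpec(1.0)
        )
        interior = out.voxels[6:-6, 6:-6, 6:-6]
        assert np.isclose(interior.var(), k2, rtol=0.1)

    def test_shift_invariance_in_interior(self, rng):
        vox = np.zeros((24, 24, 24))
        vox[8:12, 8:12, 8:12] = rng.uniform(1, 5, size=(4, 4, 4))
        a = gaussian_smooth(make_suv(vox)).voxels
        b = gaussian_smooth(make_suv(np.roll(vox, 3, axis=0))).voxels
        assert np.allclose(np.roll(a, 3, axis=0)[6:-6, 6:-6, 6:-6],
                           b[6:-6, 6:-6, 6:-6], atol=1e-9)

    def test_rejects_bad_sigma_and_anisotropic_grid(self):
        with pytest.raises(ParameterError):
            GaussianKernelSpec(sigma_vox=0.0)
        aniso = SUVVolume(np.ones((4, 4, 4)), (2.0, 2.0, 5.0))
        with pytest.raises(Exception):
            gaussian_smooth(aniso)


class TestThresholdSUV:
    def test_all_below_threshold_gives_empty_mask(self):
        mask = threshold_suv(make_suv(np.full((4, 4, 4), 2.9)))
        assert not mask.voxels.any()

    def test_threshold_is_inclusive(self):
        vox = np.full((3, 3, 3), 1.0)
        vox[1, 1, 1] = 3.0
        mask = threshold_suv(make_suv(vox), 3.0)
        assert mask.voxels[1, 1, 1]
        assert mask.voxels.sum() == 1

    def test_mask_cardinality_matches_direct_count(self, rng):
        vox = rng.uniform(0, 6, size=(10, 10, 10))
        mask = threshold_suv(make_suv(vox), 3.0)
        assert mask.voxels.sum() == int((vox >= 3.0).sum())

    @given(st.floats(min_value=0.5, max_value=8.0), st.floats(min_value=0.0, max_value=4.0))
    def test_monotone_in_threshold(self, thr, delta):
        rng = np.random.default_rng(7)
        vol = make_suv(rng.uniform(0, 10, size=(6, 6, 6)))
        low = threshold_suv(vol, thr).voxels
        high = threshold_suv(vol, thr + delta).voxels
        assert not (high & ~low).any()

    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(ParameterError):
            threshold_suv(make_suv(np.ones((2, 2, 2))), 0.0)


class TestFullChain:
    def test_uniform_organ_volume_recovered_within_ten_percent(self):
        # single sphere of SUV 5 (radius 12 voxels) on zero background: the
        # thresholded mask volume stays within 10% of the organ volume
        shape = (40, 40, 40)
        organ = sphere_mask(shape, (20, 20, 20), 12.0)
        suv_field = np.where(organ, 5.0, 0.0)
        weight_g, dose_bq = 60000.0, 3e8
        activity = suv_field * dose_bq / weight_g  # t = 0
        scan = PETScan(activity, (5.0,) * 3, weight_g, dose_bq, elapsed_min=0.0)
        smoothed, mask = preprocess(scan)
        assert abs(int(mask.voxels.sum()) - int(organ.sum())) / organ.sum() < 0.10
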