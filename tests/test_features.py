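"""First-order, shape and texture radiomics features."""
import numpy as np
import pytest

from petavid.features import (
    CORE28_NAMES,
    DIRECTIONS_13,
    FIRST_ORDER_NAMES,
    FULL62_NAMES,
    GLCM_NAMES,
    GLRLM_NAMES,
    RadiomicsExtractor,
    SHAPE_NAMES,
    compute_features,
    discretize,
    first_order_features,
    glcm_matrix,
    glcm_statistics,
    glrlm_matrix,
    glrlm_statistics,
    max_diameter_3d,
    shape_features,
    shape_indices,
    surface_mesh,
    texture_features,
    _level_volume,
)
from petavid.volumes import ParameterError

from conftest import region_from_mask, region_from_values, sphere_mask
from oracles import first_order_oracle, glcm_oracle_matrix, glrlm_oracle_matrix


class TestDiscretize:
    def test_constant_region_maps_to_level_one(self):
        r = region_from_values(np.full((2, 2, 2), 4.0))
        d = discretize(r, 8)
        assert np.all(d.gray_levels == 1)

    def test_four_values_two_levels(self):
        r = region_from_values(np.array([3.0, 4.0, 5.0, 6.0]))
        d = discretize(r, 2)
        assert list(d.gray_levels) == [1, 1, 2, 2]

    def test_single_level_rejected(self):
        r = region_from_values(np.array([1.0, 2.0]))
        with pytest.raises(ParameterError):
            discretize(r, 1)

    def test_edges_span_region_range(self):
        r = region_from_values(np.array([2.0, 9.0, 5.0]))
        d = discretize(r, 4)
        assert d.bin_edges[0] == 2.0 and d.bin_edges[-1] == 9.0
        assert np.all(np.diff(d.bin_edges) > 0)


class TestFirstOrder:
    def test_constant_region_conventions(self):
        n = 24
        r = region_from_values(np.full((4, 3, 2), 4.0))
        f = first_order_features(r)
        assert f["mean"] == 4.0
        assert f["variance"] == 0.0
        assert f["energy"] == pytest.approx(16.0 * n)
        assert f["entropy"] == 0.0
        assert f["uniformity"] == 1.0
        assert f["skewness"] == 0.0
        assert f["kurtosis"] == 0.0

    def test_two_sample_hand_arithmetic(self):
        r = region_from_values(np.array([2.0, 4.0]))
        f = first_order_features(r)
        assert f["mean"] == 3.0
        assert f["root_mean_square"] == pytest.approx(np.sqrt(10.0))
        assert f["energy"] == pytest.approx(20.0)
        assert f["range"] == 2.0
        assert f["mean_absolute_deviation"] == 1.0

    def test_matches_histogram_oracle(self, small_random_region):
        disc = discretize(small_random_region, 16)
        ours = first_order_features(small_random_region, disc)
        expected = first_order_oracle(
            small_random_region.suv_values, disc.gray_levels, 16
        )
        for name in FIRST_ORDER_NAMES:
            assert ours[name] == pytest.approx(expected[name], abs=1e-9), name

    def test_scale_property(self, small_random_region):
        # doubling SUVs doubles the linear stats, quadruples the quadratic
        # ones and leaves the dimensionless ones unchanged
        import dataclasses

        r = small_random_region
        r2 = dataclasses.replace(r, suv_values=2 * r.suv_values)
        a, b = first_order_features(r), first_order_features(r2)
        for name in ("mean", "median", "maximum", "minimum", "range",
                     "mean_absolute_deviation", "standard_deviation",
                     "root_mean_square"):
            assert b[name] == pytest.approx(2 * a[name])
        for name in ("variance",):
            assert b[name] == pytest.approx(4 * a[name])
        assert b["energy"] == pytest.approx(4 * a["energy"])
        for name in ("skewness", "kurtosis", "entropy", "uniformity"):
            assert b[name] == pytest.approx(a[name], abs=1e-9)


class TestShape:
    def test_cube_compactness_with_exact_surface_oracle(self):
        # compactness2 of a cube is pi/6 given the exact surface 6a^2
        a_mm = 50.0
        v = a_mm**3
        area = 6 * a_mm**2
        idx = shape_indices(v, area)
        assert idx["compactness2"] == pytest.approx(np.pi / 6, abs=1e-12)
        assert idx["sphericity"] == pytest.approx((np.pi / 6) ** (1 / 3), abs=1e-12)

    def test_cube_mesh_bounded_between_sharp_cube_and_sphere(self):
        # the anti-aliased mesh rounds the cube's corners, so its
        # compactness2 lies strictly between the sharp cube (pi/6) and the
        # sphere limit (1)
        mask = np.zeros((14, 14, 14), dtype=bool)
        mask[2:12, 2:12, 2:12] = True
        f = shape_features(region_from_mask(mask, np.where(mask, 5.0, 0.0)))
        assert np.pi / 6 < f["compactness2"] < 1.0

    def test_digitized_sphere_near_unit_sphericity(self):
        shape = (26, 26, 26)
        mask = sphere_mask(shape, (12.5, 12.5, 12.5), 10.0)
        f = shape_features(region_from_mask(mask, np.where(mask, 5.0, 0.0)))
        assert 0.95 <= f["sphericity"] <= 1.05
        assert 0.95 <= f["spherical_disproportion"] <= 1.05
        # compactness2 = sphericity^3 exactly, by construction of both
        assert f["compactness2"] == pytest.approx(f["sphericity"] ** 3, abs=1e-6)

    def test_volume_in_ml(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[1:11, 1:11, 1:11] = True  # 1000 voxels at 5 mm = 125 mL
        f = shape_features(region_from_mask(mask, np.where(mask, 5.0, 0.0)))
        assert f["volume"] == pytest.approx(125.0)

    def test_centroid_of_symmetric_region_is_half(self):
        shape = (16, 16, 16)
        mask = sphere_mask(shape, (7.5, 7.5, 7.5), 5.0)
        f = shape_features(region_from_mask(mask, np.where(mask, 4.0, 0.0)))
        for name in ("centroid_x", "centroid_y", "centroid_z"):
            assert f[name] == pytest.approx(0.5, abs=1e-9)

    def test_max_diameter_of_sphere(self):
        shape = (26, 26, 26)
        mask = sphere_mask(shape, (12.5, 12.5, 12.5), 10.0)
        f = shape_features(region_from_mask(mask, np.where(mask, 5.0, 0.0)))
        # mesh diameter of a 10-voxel-radius sphere at 5 mm spacing
        assert f["max_diameter_3d"] == pytest.approx(100.0, rel=0.05)

    def test_translation_invariance_and_centroid_shift(self):
        shape = (24, 24, 24)
        m1 = sphere_mask(shape, (8, 8, 8), 4.0)
        m2 = sphere_mask(shape, (13, 11, 10), 4.0)
        suv1 = np.where(m1, 5.0, 0.0)
        suv2 = np.where(m2, 5.0, 0.0)
        f1 = shape_features(region_from_mask(m1, suv1))
        f2 = shape_features(region_from_mask(m2, suv2))
        for name in ("volume", "surface_area", "sphericity", "compactness1",
                     "compactness2", "max_diameter_3d"):
            assert f1[name] == pytest.approx(f2[name], rel=1e-9), name
        assert f2["centroid_x"] - f1["centroid_x"] == pytest.approx(5 / 24, abs=1e-9)
        assert f2["centroid_y"] - f1["centroid_y"] == pytest.approx(3 / 24, abs=1e-9)
        assert f2["centroid_z"] - f1["centroid_z"] == pytest.approx(2 / 24, abs=1e-9)

    def test_major_axis_of_elongated_region(self):
        mask = np.zeros((20, 8, 8), dtype=bool)
        mask[2:18, 3:5, 3:5] = True
        f = shape_features(region_from_mask(mask, np.where(mask, 5.0, 0.0)))
        axis = np.array([f["major_axis_x"], f["major_axis_y"], f["major_axis_z"]])
        assert abs(axis[0]) > 0.99
        assert np.isclose(np.linalg.norm(axis), 1.0)

    def test_major_axis_sign_fixed_nonnegative_z(self):
        mask = np.zeros((8, 8, 20), dtype=bool)
        mask[3:5, 3:5, 2:18] = True
        f = shape_features(region_from_mask(mask, np.where(mask, 5.0, 0.0)))
        assert f["major_axis_z"] > 0.99

    def test_single_voxel_region(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        f = shape_features(region_from_mask(mask, np.where(mask, 5.0, 0.0)))
        assert f["volume"] == pytest.approx(0.125)
        assert f["surface_area"] > 0
        assert (f["major_axis_x"], f["major_axis_y"], f["major_axis_z"]) == (0, 0, 1)

    def test_rotation_about_z_permutes_major_axis(self):
        mask = np.zeros((20, 20, 8), dtype=bool)
        mask[2:18, 9:11, 3:5] = True  # elongated along x
        suv = np.where(mask, 5.0, 0.0)
        f = shape_features(region_from_mask(mask, suv))
        rot = np.rot90(mask, axes=(0, 1))  # now elongated along y
        f_rot = shape_features(region_from_mask(rot, np.where(rot, 5.0, 0.0)))
        assert abs(f["major_axis_x"]) == pytest.approx(abs(f_rot["major_axis_y"]), abs=1e-6)
        assert f["sphericity"] == pytest.approx(f_rot["sphericity"], rel=1e-6)


class TestTexture:
    def test_constant_region_collapses(self):
        r = region_from_values(np.full((3, 3, 3), 4.0))
        f = texture_features(r)
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_energy"] == 1.0
        assert f["glcm_correlation"] == 0.0  # logged degenerate convention
        # one run per line: run percentage equals n_runs / n_voxels per
        # direction, averaged; for an axis direction on a 3x3x3 cube that is
        # 9 runs / 27 voxels
        d = (1, 0, 0)
        disc = discretize(r, 8)
        mat = glrlm_matrix(_level_volume(r, disc), 8, d)
        stats = glrlm_statistics(mat, r.n_voxels)
        assert stats["glrlm_run_percentage"] == pytest.approx(9 / 27)

    def test_alternating_pattern_single_direction_contrast(self):
        # 1-D two-level alternating pattern: only off-diagonal co-occurrences,
        # contrast = 1
        vals = np.array([3.0, 6.0] * 6)
        r = region_from_values(vals)
        disc = discretize(r, 2)
        lev = _level_volume(r, disc)
        p = glcm_matrix(lev, 2, (1, 0, 0))
        assert p[0, 0] == 0 and p[1, 1] == 0
        stats = glcm_statistics(p)
        assert stats["glcm_contrast"] == pytest.approx(1.0)
        assert stats["glcm_dissimilarity"] == pytest.approx(1.0)

    @pytest.mark.parametrize("direction", [(1, 0, 0), (0, 1, 1), (1, -1, 1)])
    def test_glcm_matches_pair_enumeration_oracle(self, small_random_region, direction):
        n = 6
        disc = discretize(small_random_region, n)
        lev = _level_volume(small_random_region, disc)
        ours = glcm_matrix(lev, n, direction)
        oracle = glcm_oracle_matrix(lev, n, direction)
        assert np.allclose(ours, oracle, atol=1e-12)

    @pytest.mark.parametrize("direction", [(1, 0, 0), (0, 0, 1), (1, 1, -1)])
    def test_glrlm_matches_run_enumeration_oracle(self, small_random_region, direction):
        n = 4
        disc = discretize(small_random_region, n)
        lev = _level_volume(small_random_region, disc)
        ours = glrlm_matrix(lev, n, direction)
        oracle = glrlm_oracle_matrix(lev, n, direction)
        # pad to common width
        w = max(ours.shape[1], oracle.shape[1])
        ours = np.pad(ours, ((0, 0), (0, w - ours.shape[1])))
        oracle = np.pad(oracle, ((0, 0), (0, w - oracle.shape[1])))
        assert np.array_equal(ours, oracle)

    def test_run_total_voxel_count_identity(self, small_random_region):
        # sum over the GLRLM of gray-level g, length l of l * R(g, l) equals
        # the region voxel count, for every direction
        disc = discretize(small_random_region, 5)
        lev = _level_volume(small_random_region, disc)
        for d in DIRECTIONS_13:
            mat = glrlm_matrix(lev, 5, d)
            lengths = np.arange(1, mat.shape[1] + 1)
            assert int((mat * lengths).sum()) == small_random_region.n_voxels

    def test_texture_requires_two_voxels(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        r = region_from_mask(mask, np.full((3, 3, 3), 4.0))
        with pytest.raises(ParameterError):
            texture_features(r)

    def test_translation_invariance(self, rng):
        shape = (14, 14, 14)
        vals = rng.uniform(3, 9, size=(4, 4, 4))
        m1 = np.zeros(shape, dtype=bool)
        m1[1:5, 1:5, 1:5] = True
        suv1 = np.zeros(shape)
        suv1[1:5, 1:5, 1:5] = vals
        m2 = np.roll(m1, (5, 3, 2), axis=(0, 1, 2))
        suv2 = np.roll(suv1, (5, 3, 2), axis=(0, 1, 2))
        f1 = texture_features(region_from_mask(m1, suv1))
        f2 = texture_features(region_from_mask(m2, suv2))
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], abs=1e-9), name


class TestAssembly:
    def test_feature_sets_have_documented_sizes(self):
        assert len(FIRST_ORDER_NAMES) == 14
        assert len(SHAPE_NAMES) == 14
        assert len(GLCM_NAMES) == 23
        assert len(GLRLM_NAMES) == 11
        assert len(CORE28_NAMES) == 28
        assert len(FULL62_NAMES) == 62

    def test_compute_features_order_and_finiteness(self, small_random_region):
        f = compute_features(small_random_region, "full62")
        assert list(f) == list(FULL62_NAMES)
        assert all(np.isfinite(v) for v in f.values())

    def test_extractor_transform_dataframe(self, small_random_region):
        ext = RadiomicsExtractor(feature_set="core28").fit([])
        df = ext.transform([small_random_region])
        assert list(df.columns) == list(CORE28_NAMES)
        assert df.index.tolist() == [small_random_region.id]

    def test_extractor_sklearn_params_roundtrip(self):
        ext = RadiomicsExtractor(feature_set="full62", n_bins=8)
        params = ext.get_params()
        assert params == {"feature_set": "full62", "n_bins": 8}
        ext.set_params(n_bins=4)
        assert ext.n_bins == 4
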