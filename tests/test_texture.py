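import numpy as np
import pandas as pd
import pytest

from pkdrad.imaging import ROI, SegmentationMask
from pkdrad.texture import (
    AGGREGATION_MODES,
    GLCM_FEATURES,
    GreyLevelImage,
    aggregate_texture,
    build_cooccurrence,
    discretize_levels,
    glcm_cluster_tendency,
    glcm_correlation,
    glcm_feature_suite,
    intensity_features,
    morphology_features,
    zscore_table,
)

from .conftest import make_roi
from .oracles import aggregate_naive, glcm_features_naive, pair_count_matrix


def roi_from_values(values):
    values = np.asarray(values, dtype=float)
    coords = np.column_stack(
        [np.zeros(len(values), int), np.zeros(len(values), int), np.arange(len(values))]
    )
    return ROI(coordinates=coords, values=values, spacing=(1.0, 1.0, 1.0))


def img_from_levels(levels_2d, ng=None):
    lv = np.asarray(levels_2d, dtype=int)[None, :, :]
    return GreyLevelImage(levels=lv, ng=int(ng or lv.max()), spacing=(1, 1, 1))


def random_level_image(rng, shape=(3, 8, 8), ng=6, fill=0.7):
    lv = rng.integers(1, ng + 1, size=shape)
    lv[rng.random(shape) > fill] = 0
    if not (lv > 0).any():
        lv[0, 0, 0] = 1
    return GreyLevelImage(levels=lv, ng=ng, spacing=(1, 1, 1))


class TestDiscretize:
    def test_none_maps_rounded_hu(self):
        img = discretize_levels(roi_from_values([30, 30, 35]), "none")
        assert sorted(img.levels[img.levels > 0].tolist()) == [1, 1, 6]
        assert img.ng == 6

    def test_fixed_bin_count_equal_width(self):
        img = discretize_levels(roi_from_values([0, 10, 20, 30]), "fixed_bin_count", 2)
        assert sorted(img.levels[img.levels > 0].tolist()) == [1, 1, 2, 2]

    def test_fixed_bin_size(self):
        img = discretize_levels(roi_from_values([0, 4.9, 5, 14.9]), "fixed_bin_size", 5)
        assert sorted(img.levels[img.levels > 0].tolist()) == [1, 1, 2, 3]

    @pytest.mark.parametrize("method,param", [("none", None), ("fixed_bin_size", 5), ("fixed_bin_count", 4)])
    def test_constant_roi_single_level(self, method, param):
        img = discretize_levels(roi_from_values([7.0, 7.0, 7.0]), method, param)
        assert img.ng == 1 and set(img.levels[img.levels > 0]) == {1}

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            discretize_levels(roi_from_values([1, 2]), "fixed_bin_size", 0)
        with pytest.raises(ValueError):
            discretize_levels(roi_from_values([1, 2]), "fixed_bin_count", 0)


class TestCooccurrence:
    def test_single_pair(self):
        img = img_from_levels([[1, 2]])
        cm = build_cooccurrence(img, 0, (0, 1)).normalize()
        assert cm.matrix[0, 1] == 0.5 and cm.matrix[1, 0] == 0.5

    def test_constant_square(self):
        img = img_from_levels([[1, 1], [1, 1]])
        cm = build_cooccurrence(img, 0, (0, 1)).normalize()
        assert cm.matrix[0, 0] == 1.0

    def test_matches_pair_enumeration_oracle(self, rng):
        img = random_level_image(rng, shape=(1, 8, 8))
        for direction in [(0, 1), (1, 1), (1, 0), (1, -1)]:
            cm = build_cooccurrence(img, 0, direction)
            expected = pair_count_matrix(img.levels, img.ng, 0, direction)
            assert np.array_equal(cm.matrix, expected)

    def test_empty_direction_flagged(self):
        img = img_from_levels([[1], [0]], ng=1)  # single column: no horizontal pair
        cm = build_cooccurrence(img, 0, (0, 1))
        assert cm.empty


class TestGlcmFeatures:
    def test_correlation_single_pair_is_minus_one(self):
        cm = build_cooccurrence(img_from_levels([[1, 2]]), 0, (0, 1)).normalize()
        assert glcm_correlation(cm) == pytest.approx(-1.0)

    def test_correlation_constant_image_convention(self):
        cm = build_cooccurrence(img_from_levels([[1, 1]]), 0, (0, 1)).normalize()
        assert glcm_correlation(cm) == 1.0

    def test_cluster_tendency_hand_values(self):
        # constant image: all mass at (1,1), i+j-2mu = 0
        cm = build_cooccurrence(img_from_levels([[1, 1]]), 0, (0, 1)).normalize()
        assert glcm_cluster_tendency(cm) == pytest.approx(0.0)
        # single pair [1,2]: both entries have i+j = 3 = 2mu
        cm = build_cooccurrence(img_from_levels([[1, 2]]), 0, (0, 1)).normalize()
        assert glcm_cluster_tendency(cm) == pytest.approx(0.0)
        # [1,1,2]: p(1,1)=.5, p(1,2)=p(2,1)=.25, mu=1.25 -> sum=0.25
        cm = build_cooccurrence(img_from_levels([[1, 1, 2]]), 0, (0, 1)).normalize()
        assert glcm_cluster_tendency(cm) == pytest.approx(0.25)

    def test_suite_trivial_values(self):
        cm = build_cooccurrence(img_from_levels([[1, 1], [1, 1]]), 0, (0, 1)).normalize()
        suite = glcm_feature_suite(cm)
        assert suite["contrast"] == 0 and suite["asm"] == 1 and suite["joint.entr"] == 0
        cm = build_cooccurrence(img_from_levels([[1, 2]]), 0, (0, 1)).normalize()
        suite = glcm_feature_suite(cm)
        assert suite["contrast"] == pytest.approx(1.0)
        assert suite["joint.avg"] == pytest.approx(1.5)

    def test_suite_matches_naive_double_loop(self, rng):
        for _ in range(5):
            img = random_level_image(rng, shape=(1, 6, 6), ng=5)
            cm = build_cooccurrence(img, 0, (1, 0))
            if cm.empty:
                continue
            got = glcm_feature_suite(cm.normalize())
            want = glcm_features_naive(cm.matrix / cm.matrix.sum())
            for k in GLCM_FEATURES:
                assert got[k] == pytest.approx(want[k], abs=1e-12), k

    def test_level_shift_invariance(self, rng):
        """corr and cluster tendency are unchanged when all levels shift by k."""
        img = random_level_image(rng, shape=(1, 7, 7), ng=4)
        shifted = GreyLevelImage(
            levels=np.where(img.levels > 0, img.levels + 3, 0), ng=img.ng + 3, spacing=img.spacing
        )
        for a, b in [(img, shifted)]:
            ca = build_cooccurrence(a, 0, (0, 1)).normalize()
            cb = build_cooccurrence(b, 0, (0, 1)).normalize()
            assert glcm_correlation(ca) == pytest.approx(glcm_correlation(cb), abs=1e-10)
            assert glcm_cluster_tendency(ca) == pytest.approx(glcm_cluster_tendency(cb), abs=1e-10)

    def test_unnormalized_rejected(self):
        cm = build_cooccurrence(img_from_levels([[1, 2]]), 0, (0, 1))
        with pytest.raises(ValueError):
            glcm_correlation(cm)


class TestAggregation:
    def test_modes_agree_on_single_slice_single_direction(self):
        # a 2x1 slice has pairs only in the vertical direction
        img = GreyLevelImage(levels=np.array([[[1], [2]]]), ng=2, spacing=(1, 1, 1))
        vals = [aggregate_texture(img, GLCM_FEATURES, m) for m in AGGREGATION_MODES]
        for other in vals[1:]:
            for k in GLCM_FEATURES:
                assert vals[0][k] == pytest.approx(other[k], abs=1e-12)

    def test_identical_slices_average_equals_single(self, rng):
        one = random_level_image(rng, shape=(1, 6, 6), ng=4)
        two = GreyLevelImage(
            levels=np.concatenate([one.levels, one.levels]), ng=one.ng, spacing=(1, 1, 1)
        )
        a = aggregate_texture(one, GLCM_FEATURES, "2d_avg")
        b = aggregate_texture(two, GLCM_FEATURES, "2d_avg")
        for k in GLCM_FEATURES:
            assert a[k] == pytest.approx(b[k], abs=1e-12)

    @pytest.mark.parametrize("mode", AGGREGATION_MODES)
    def test_matches_naive_aggregation(self, rng, mode):
        for _ in range(3):
            img = random_level_image(rng)
            got = aggregate_texture(img, GLCM_FEATURES, mode)
            want = aggregate_naive(img.levels, img.ng, mode)
            for k in GLCM_FEATURES:
                assert got[k] == pytest.approx(want[k], abs=1e-10), (mode, k)

    def test_cross_check_against_skimage(self, rng):
        """On a fully-covered rectangular slice our counts match the
        reference greycomatrix implementation."""
        from skimage.feature import graycomatrix

        lv = rng.integers(1, 5, size=(7, 9))
        img = GreyLevelImage(levels=lv[None], ng=4, spacing=(1, 1, 1))
        # skimage angle 0 is the (0,1) offset; symmetric counts
        sk = graycomatrix(lv.astype(np.uint8), [1], [0], levels=5, symmetric=True)
        ours = build_cooccurrence(img, 0, (0, 1)).matrix
        assert np.array_equal(ours, sk[1:, 1:, 0, 0])


class TestIntensityFeatures:
    def test_trivial_constant(self):
        f = intensity_features(roi_from_values([2, 2, 2]))
        assert f["F_stat.mean"] == 2 and f["F_stat.var"] == 0 and f["F_stat.energy"] == 12

    def test_direct_computation(self):
        f = intensity_features(roi_from_values([1, 2, 3, 4]))
        assert f["F_stat.mean"] == pytest.approx(2.5)
        assert f["F_stat.var"] == pytest.approx(1.25)  # population variance
        assert f["F_stat.range"] == 3
        assert f["F_stat.rms"] == pytest.approx(np.sqrt(30 / 4))

    def test_order_invariance(self, rng):
        vals = rng.normal(size=20)
        f1 = intensity_features(roi_from_values(vals))
        f2 = intensity_features(roi_from_values(vals[::-1]))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-12), k


class TestMorphology:
    @staticmethod
    def _mask(labels, spacing=(1.0, 1.0, 1.0)):
        return SegmentationMask(np.asarray(labels, bool), "union", spacing)

    def test_single_voxel(self):
        labels = np.zeros((3, 3, 3))
        labels[1, 1, 1] = 1
        f = morphology_features(self._mask(labels))
        assert f["F_morph.vol"] == 1 and f["F_morph.area"] == 6
        assert f["F_morph.sphericity"] == pytest.approx(np.pi ** (1 / 3) * 6 ** (2 / 3) / 6)

    def test_two_voxel_bar(self):
        labels = np.zeros((4, 3, 3))
        labels[1, 1, 1] = labels[2, 1, 1] = 1
        f = morphology_features(self._mask(labels))
        assert f["F_morph.vol"] == 2 and f["F_morph.area"] == 10

    def test_anisotropic_spacing(self):
        labels = np.zeros((3, 3, 3))
        labels[1, 1, 1] = 1
        f = morphology_features(self._mask(labels, spacing=(2.0, 1.0, 1.0)))
        assert f["F_morph.vol"] == 2.0
        assert f["F_morph.area"] == pytest.approx(2 * 1 * 1 + 4 * 2 * 1)

    def test_translation_invariant_volume(self, rng):
        labels = np.zeros((5, 5, 5))
        labels[1:3, 1:3, 1:3] = 1
        shifted = np.roll(labels, (1, 1, 1), axis=(0, 1, 2))
        f1 = morphology_features(self._mask(labels))
        f2 = morphology_features(self._mask(shifted))
        assert f1["F_morph.vol"] == f2["F_morph.vol"]
        assert f1["F_morph.area"] == f2["F_morph.area"]


class TestZscore:
    def test_unit_column(self):
        out = zscore_table(pd.DataFrame({"f": [1.0, 2.0, 3.0], "g": [2.0, 0.0, 1.0]}))
        assert np.allclose(out["f"], [-1, 0, 1])

    def test_idempotent(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 5.0, 3.0], "g": [0.1, -2.0, 1.0, 0.5]})
        once = zscore_table(df)
        twice = zscore_table(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"f": [5.0, 5.0, 5.0], "g": [1.0, 2.0, 4.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_table(df)
        assert list(out.columns) == ["g"]

    def test_all_constant_rejected(self):
        df = pd.DataFrame({"f": [5.0, 5.0], "g": [1.0, 1.0]})
        with pytest.raises(ValueError):
            zscore_table(df)

    def test_moments(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        z = zscore_table(df)
        assert np.allclose(z.mean(), 0, atol=1e-10)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-10)
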