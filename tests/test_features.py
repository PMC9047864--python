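"""Feature bank: discretization, per-class hand examples, invariants, and
agreement with the brute-force reference implementation."""

import math

import numpy as np
import pytest

import _reference as ref
from conftest import random_phantom, roi, volume
from radrepro import ALL_FEATURE_NAMES, FEATURE_CLASSES, extract_all
from radrepro.features import (
    discretize_fixed_bin_width,
    first_order_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    shape_features,
)
from radrepro.features.matrices import DIRECTIONS_13, glcm_stack, glrlm_stack
from radrepro.features.texture import glcm_features


def _disc(values, spacing=(1.0, 1.0, 1.0), width=25.0):
    arr = np.asarray(values, dtype=float)
    img = volume(arr, spacing)
    return discretize_fixed_bin_width(img, roi(np.ones(arr.shape), spacing), width)


class TestDiscretization:
    def test_floor_rule_hand_example(self):
        d = _disc(np.array([0.0, 10.0, 30.0, 60.0]).reshape(4, 1, 1))
        assert d.roi_levels.tolist() == [1, 1, 2, 3]
        assert d.n_levels == 3

    def test_constant_roi_single_level(self):
        d = _disc(np.full((3, 3, 1), 42.0))
        assert d.n_levels == 1
        assert set(d.roi_levels.tolist()) == {1}

    def test_negative_intensities(self):
        d = _disc(np.array([-30.0, -10.0]).reshape(2, 1, 1))
        assert d.roi_levels.tolist() == [1, 2]

    def test_empty_mask_rejected(self):
        img = volume(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            discretize_fixed_bin_width(img, roi(np.zeros((3, 3, 3))), 25.0)


class TestFirstOrder:
    def test_constant_roi_degenerate_conventions(self):
        f = first_order_features(_disc(np.full((2, 2, 2), 7.0)))
        assert f["Variance"] == 0.0
        assert f["Entropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["Uniformity"] == pytest.approx(1.0)
        assert f["Skewness"] == 0.0

    def test_hand_arithmetic_1234(self):
        f = first_order_features(_disc(np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)))
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Range"] == pytest.approx(3.0)
        assert f["RootMeanSquared"] == pytest.approx(math.sqrt(7.5))

    def test_emits_18_names(self):
        f = first_order_features(_disc(np.arange(8.0).reshape(2, 2, 2)))
        assert len(f) == 18


class TestShape:
    def test_large_ball_sphericity_near_one(self):
        n = 41
        g = np.ogrid[:n, :n, :n]
        ball = sum((a - n // 2) ** 2 for a in g) <= 18**2
        f = shape_features(roi(ball))
        assert 0.95 < f["Sphericity"] <= 1.0

    def test_single_voxel_volume_and_degenerate_axes(self):
        arr = np.zeros((5, 5, 5))
        arr[2, 2, 2] = 1
        with pytest.warns(UserWarning, match="degenerate"):
            f = shape_features(roi(arr))
        assert f["VoxelVolume"] == pytest.approx(1.0)
        assert f["MajorAxisLength"] == 0.0

    def test_emits_14_names(self, rng):
        _, m = random_phantom(rng)
        assert len(shape_features(m)) == 14

    def test_ellipsoid_axis_lengths_analytic(self):
        # solid ellipsoid with semi-axes (a,b,c): eigenvalues a^2/5 etc.,
        # axis length 4*sqrt(lambda) -> 4a/sqrt(5)
        n = 61
        g = np.ogrid[:n, :n, :n]
        a, b, c = 24.0, 16.0, 10.0
        ell = (
            ((g[0] - n // 2) / a) ** 2 + ((g[1] - n // 2) / b) ** 2 + ((g[2] - n // 2) / c) ** 2
        ) <= 1
        f = shape_features(roi(ell))
        assert f["MajorAxisLength"] == pytest.approx(4 * a / math.sqrt(5), rel=0.02)
        assert f["LeastAxisLength"] == pytest.approx(4 * c / math.sqrt(5), rel=0.02)
        assert f["Flatness"] == pytest.approx(c / a, rel=0.02)


class TestGlcm:
    def test_single_voxel_zero_matrix_convention(self):
        with pytest.warns(UserWarning, match="degenerate"):
            f = glcm_features(_disc(np.array([[[5.0]]])))
        assert f["JointEntropy"] == 0.0
        assert len(f) == 24

    def test_constant_2x2x1_all_mass_at_origin(self):
        f = glcm_features(_disc(np.full((2, 2, 1), 30.0)))
        assert f["MaximumProbability"] == pytest.approx(1.0)
        assert f["JointEntropy"] == pytest.approx(0.0, abs=1e-9)

    def test_two_level_strip_hand_counts(self):
        # levels 1,1,2 along one axis: direction (1,0,0) pairs (1,1),(1,2)
        d = _disc(np.array([0.0, 10.0, 30.0]).reshape(3, 1, 1))
        stack = glcm_stack(d.levels, d.n_levels)
        mat = stack[DIRECTIONS_13.index((1, 0, 0))]
        assert mat.tolist() == [[2.0, 1.0], [1.0, 0.0]]


class TestGlrlm:
    def test_single_run_of_four(self):
        d = _disc(np.full((4, 1, 1), 10.0))
        stack = glrlm_stack(d.levels, d.n_levels)
        mat = stack[DIRECTIONS_13.index((1, 0, 0))]
        assert mat[0, 3] == 1.0 and mat.sum() == 1.0
        sre = (mat[0, 3] / 16) / mat.sum()
        assert sre == pytest.approx(1.0 / 16.0)

    def test_constant_roi_glnn_is_one(self):
        f = glrlm_features(_disc(np.full((3, 3, 3), 5.0)))
        assert f["GrayLevelNonUniformityNormalized"] == pytest.approx(1.0)
        assert len(f) == 16


class TestGlszm:
    def test_constant_3x3x1_single_zone(self):
        f = glszm_features(_disc(np.full((3, 3, 1), 50.0)))
        assert f["LargeAreaEmphasis"] == pytest.approx(81.0)  # one zone of size 9
        assert f["ZonePercentage"] == pytest.approx(1.0 / 9.0)

    def test_alternating_row_all_singleton_zones(self):
        vals = np.array([0.0, 25.0] * 4).reshape(1, 8, 1)
        f = glszm_features(_disc(vals))
        assert f["SmallAreaEmphasis"] == pytest.approx(1.0)
        assert len(f) == 16


class TestGldm:
    def test_constant_3x3x1_hand_histogram(self):
        # dependencies (neighbour count + 1): 4 corners -> 4, 4 edges -> 6,
        # centre -> 9
        f = gldm_features(_disc(np.full((3, 3, 1), 10.0)))
        probs = [4 / 9, 4 / 9, 1 / 9]
        expected = -sum(p * math.log2(p + np.spacing(1.0)) for p in probs)
        assert f["DependenceEntropy"] == pytest.approx(expected, rel=1e-12)
        assert f["LargeDependenceEmphasis"] == pytest.approx(
            (4 * 16 + 4 * 36 + 81) / 9.0
        )

    def test_single_voxel(self):
        f = gldm_features(_disc(np.array([[[5.0]]])))
        assert f["DependenceEntropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["LargeDependenceEmphasis"] == pytest.approx(1.0)
        assert len(f) == 14


class TestNgtdm:
    def test_constant_roi_contrast_zero(self):
        f = ngtdm_features(_disc(np.full((3, 3, 1), 10.0)))
        assert f["Contrast"] == 0.0
        assert len(f) == 5

    def test_two_level_strip_hand_value(self):
        # levels 1,1,2,2,1,1 -> s_1 = 1.0, s_2 = 1.0, p = (2/3, 1/3)
        vals = np.array([0.0, 0.0, 25.0, 25.0, 0.0, 0.0]).reshape(6, 1, 1)
        f = ngtdm_features(_disc(vals))
        assert f["Contrast"] == pytest.approx(2.0 / 27.0)


class TestBank:
    def test_cardinality_107_with_class_counts(self, rng):
        img, m = random_phantom(rng)
        vec = extract_all(img, m)
        assert len(vec) == 107
        expected = {
            "firstorder": 18,
            "glcm": 24,
            "gldm": 14,
            "glrlm": 16,
            "glszm": 16,
            "ngtdm": 5,
            "shape": 14,
        }
        for cls, count in expected.items():
            assert len(vec.by_class(cls)) == count
            assert len(FEATURE_CLASSES[cls]) == count

    def test_deterministic(self, rng):
        img, m = random_phantom(rng)
        a = extract_all(img, m).as_array()
        b = extract_all(img, m).as_array()
        assert np.array_equal(a, b)

    def test_translation_invariance(self, rng):
        img, m = random_phantom(rng, shape=(12, 12, 12))
        pad_img = np.pad(img.array, ((3, 0), (2, 1), (0, 3)), constant_values=-100.0)
        pad_m = np.pad(m.array, ((3, 0), (2, 1), (0, 3)))
        a = extract_all(img, m).as_array()
        b = extract_all(volume(pad_img), roi(pad_m)).as_array()
        np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-12)

    def test_intensity_shift_by_whole_bins_preserves_texture(self, rng):
        img, m = random_phantom(rng, shape=(12, 12, 12))
        shifted = volume(img.array + 3 * 25.0)
        a = extract_all(img, m)
        b = extract_all(shifted, m)
        for name in ALL_FEATURE_NAMES:
            cls = name.split("_")[0]
            if cls in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
                assert a[name] == pytest.approx(b[name], rel=1e-12), name

    def test_normalized_matrices_sum_to_one(self, rng):
        from radrepro.features.discretize import discretize_fixed_bin_width as disc_fn
        from radrepro.features.matrices import glszm_matrix

        for _ in range(20):
            img, m = random_phantom(rng, shape=(10, 10, 10))
            d = disc_fn(img, m, 25.0)
            stack = glcm_stack(d.levels, d.n_levels)
            for mat in stack:
                if mat.sum() > 0:
                    assert (mat / mat.sum()).sum() == pytest.approx(1.0)
            z = glszm_matrix(d.levels, d.n_levels)
            assert (z / z.sum()).sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_reference(self, seed):
        rng = np.random.default_rng(seed)
        img, m = random_phantom(rng, shape=(10, 10, 10))
        vec = extract_all(img, m)
        d = ref.discretize(img.array, m.array, 25.0)
        ng = int(d.max())
        expected = {}
        expected.update(
            {f"firstorder_{k}": v for k, v in ref.firstorder(img.array, m.array, 25.0, m.spacing).items()}
        )
        expected.update({f"glcm_{k}": v for k, v in ref.glcm_features(d, ng).items()})
        expected.update({f"glrlm_{k}": v for k, v in ref.glrlm_features(d, ng).items()})
        expected.update({f"glszm_{k}": v for k, v in ref.glszm_features(d, ng).items()})
        expected.update({f"gldm_{k}": v for k, v in ref.gldm_features(d, ng).items()})
        expected.update({f"ngtdm_{k}": v for k, v in ref.ngtdm_features(d, ng).items()})
        for name, want in expected.items():
            got = vec[name]
            assert got == pytest.approx(want, rel=1e-6, abs=1e-9), name
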