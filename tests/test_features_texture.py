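import numpy as np
import pytest

from adcstab.features import ExtractionConfig
from adcstab.features.texture import (
    ANGLES_4,
    COARSENESS_CAP,
    gldm_count_matrix,
    gldm_features,
    glcm_count_matrices,
    glcm_features,
    glrlm_count_matrices,
    glrlm_features,
    glszm_count_matrix,
    glszm_features,
    ngtdm_features,
    ngtdm_table,
)

from .conftest import random_levels
from .oracles import (
    glcm_counts_brute,
    gldm_brute,
    glrlm_brute,
    glszm_zones_brute,
    ngtdm_brute,
)

CFG = ExtractionConfig()


def zones_from_matrix(P):
    zones = []
    for i, row in enumerate(P):
        for s, count in enumerate(row):
            zones.extend([(i + 1, s + 1)] * int(count))
    return sorted(zones)


class TestWorkedExamples:
    def test_glcm_two_by_two_pair_counts(self):
        levels = np.array([[1, 1], [1, 2]])
        mats = glcm_count_matrices(levels, n_levels=2)
        horizontal = mats[0]  # offset (0, 1)
        np.testing.assert_array_equal(horizontal, [[2, 1], [1, 0]])
        assert horizontal.sum() == 4  # symmetric normalizer

    def test_constant_image_glcm(self):
        levels = np.ones((4, 4), dtype=np.int64)
        f = glcm_features(levels, CFG)
        assert f["MaximumProbability"] == 1.0
        assert f["JointEntropy"] == 0.0

    def test_constant_three_by_three_runs_and_zones(self):
        levels = np.ones((3, 3), dtype=np.int64)
        horizontal = glrlm_count_matrices(levels, 1)[0]
        assert horizontal[0, 2] == 3  # one length-3 run per row
        assert horizontal.sum() == 3
        P = glszm_count_matrix(levels, 1)
        assert zones_from_matrix(P) == [(1, 9)]  # a single 9-pixel zone

    def test_single_pixel_conventions(self):
        levels = np.zeros((5, 5), dtype=np.int64)
        levels[2, 2] = 1
        assert zones_from_matrix(glszm_count_matrix(levels, 1)) == [(1, 1)]
        P = gldm_count_matrix(levels, 1)
        assert P[0, 0] == 1  # isolated pixel depends only on itself
        n_i, p_i, s_i = ngtdm_table(levels, 1)
        assert n_i[0] == 1 and s_i[0] == 0.0  # empty neighborhood adds nothing
        assert ngtdm_features(levels, CFG)["Coarseness"] == COARSENESS_CAP

    def test_gldm_interior_of_uniform_region_has_dependence_nine(self):
        levels = np.ones((5, 5), dtype=np.int64)
        P = gldm_count_matrix(levels, 1)
        assert P[0, 8] == 9  # the 3x3 interior pixels see all 8 neighbors


class TestOracleEquivalence:
    """Every texture matrix must equal naive enumeration on random images."""

    @pytest.mark.parametrize("seed", range(25))
    def test_glcm_matches_pair_enumeration(self, seed):
        levels = random_levels(np.random.default_rng(seed), (6, 6))
        ng = max(int(levels.max()), 1)
        for mat, offset in zip(glcm_count_matrices(levels, ng), ANGLES_4):
            np.testing.assert_array_equal(mat, glcm_counts_brute(levels, offset, ng))

    @pytest.mark.parametrize("seed", range(25))
    def test_glrlm_matches_run_enumeration(self, seed):
        levels = random_levels(np.random.default_rng(seed + 100), (7, 5))
        ng = max(int(levels.max()), 1)
        for mat, direction in zip(glrlm_count_matrices(levels, ng), ANGLES_4):
            np.testing.assert_array_equal(
                mat, glrlm_brute(levels, direction, ng, mat.shape[1])
            )

    @pytest.mark.parametrize("seed", range(25))
    def test_glszm_matches_flood_fill(self, seed):
        levels = random_levels(np.random.default_rng(seed + 200), (8, 8))
        ng = max(int(levels.max()), 1)
        assert zones_from_matrix(glszm_count_matrix(levels, ng)) == glszm_zones_brute(
            levels
        )

    @pytest.mark.parametrize("seed", range(25))
    def test_gldm_matches_neighbor_enumeration(self, seed):
        levels = random_levels(np.random.default_rng(seed + 300), (7, 7))
        ng = max(int(levels.max()), 1)
        np.testing.assert_array_equal(
            gldm_count_matrix(levels, ng), gldm_brute(levels, ng)
        )

    @pytest.mark.parametrize("seed", range(25))
    def test_ngtdm_matches_neighborhood_enumeration(self, seed):
        levels = random_levels(np.random.default_rng(seed + 400), (7, 7))
        ng = max(int(levels.max()), 1)
        n_i, p_i, s_i = ngtdm_table(levels, ng)
        n_ref, s_ref = ngtdm_brute(levels, ng)
        np.testing.assert_array_equal(n_i, n_ref)
        np.testing.assert_allclose(s_i, s_ref, atol=1e-10)


class TestFeatureValues:
    def test_feature_dicts_are_finite_on_textured_input(self):
        levels = random_levels(np.random.default_rng(5), (10, 10), n_levels=6)
        for fn in (glcm_features, glrlm_features, glszm_features, gldm_features,
                   ngtdm_features):
            vals = fn(levels, CFG)
            assert all(np.isfinite(v) for v in vals.values()), fn.__name__

    def test_correlation_degenerate_on_single_level(self):
        levels = np.ones((4, 4), dtype=np.int64)
        f = glcm_features(levels, CFG)
        assert np.isnan(f["Correlation"])
        assert f["MCC"] == 1.0
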