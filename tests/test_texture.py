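"""Texture-matrix families: hand-checkable fixtures and brute-force oracles."""

import numpy as np
import pytest

from oracles import (
    BRUTE_DIRECTIONS,
    brute_glcm,
    brute_gldm,
    brute_glrlm,
    brute_glszm,
    brute_ngtdm,
)
from conftest import make_disc, random_level_grid
from radiorobust.features.texture import (
    DIRECTIONS_13,
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    glcm_matrices,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glrlm_matrices,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    ngtdm_matrix,
)


def test_direction_sets_agree():
    assert sorted(DIRECTIONS_13) == sorted(BRUTE_DIRECTIONS)
    assert len(DIRECTIONS_13) == 13


def _pad_to(m, shape):
    out = np.zeros(shape)
    out[: m.shape[0], : m.shape[1]] = m
    return out


@pytest.fixture(scope="module")
def grids():
    rng = np.random.default_rng(20221229)
    return [random_level_grid(rng) for _ in range(50)]


class TestOracleEquivalence:
    """Optimized matrices equal exhaustive enumeration on random fixtures."""

    @pytest.mark.parametrize("distance", [1, 2])
    def test_glcm(self, grids, distance):
        for grid in grids:
            got = glcm_matrices(make_disc(grid), distance)
            expected = brute_glcm(grid, distance)
            assert set(got) == set(expected)
            for d in expected:
                np.testing.assert_allclose(got[d], expected[d], atol=1e-9)

    def test_glrlm(self, grids):
        for grid in grids:
            got = glrlm_matrices(make_disc(grid))
            expected = brute_glrlm(grid)
            for g, e in zip(got, expected):
                shape = np.maximum(g.shape, e.shape)
                np.testing.assert_allclose(
                    _pad_to(g, shape), _pad_to(e, shape), atol=1e-9
                )

    def test_glszm(self, grids):
        for grid in grids:
            g = glszm_matrix(make_disc(grid))
            e = brute_glszm(grid)
            shape = np.maximum(g.shape, e.shape)
            np.testing.assert_allclose(_pad_to(g, shape), _pad_to(e, shape), atol=1e-9)

    @pytest.mark.parametrize("distance", [1, 2])
    def test_ngtdm(self, grids, distance):
        for grid in grids:
            s, n = ngtdm_matrix(make_disc(grid), distance)
            es, en = brute_ngtdm(grid, distance)
            np.testing.assert_allclose(s, es, atol=1e-9)
            np.testing.assert_allclose(n, en, atol=1e-9)

    @pytest.mark.parametrize("distance", [1, 2])
    def test_gldm(self, grids, distance):
        for grid in grids:
            g = gldm_matrix(make_disc(grid), distance)
            e = brute_gldm(grid, distance)
            shape = np.maximum(g.shape, e.shape)
            np.testing.assert_allclose(_pad_to(g, shape), _pad_to(e, shape), atol=1e-9)


class TestGLCM:
    def test_two_row_fixture_single_direction(self):
        # levels [[1,1],[2,2]]: along axis 0 the pairs are (1,2) twice
        disc = make_disc([[1, 1], [2, 2]])
        mats = glcm_matrices(disc, 1)
        m = mats[(1, 0, 0)]
        np.testing.assert_allclose(m, [[0, 2], [2, 0]])
        p = m / m.sum()
        contrast = sum(
            p[i, j] * (i - j) ** 2 for i in range(2) for j in range(2)
        )
        assert contrast == pytest.approx(1.0)

    def test_constant_region_degenerate(self):
        out = glcm_features(make_disc(np.ones((3, 3, 3), dtype=int)), 1)
        assert out["Contrast"] == 0.0
        assert out["MaximumProbability"] == 1.0
        assert out["JointEntropy"] == 0.0
        assert out["JointEnergy"] == 1.0
        assert out["Correlation"] == 1.0
        assert out["MCC"] == 1.0

    def test_twenty_four_values_and_matrix_symmetry(self, rng):
        grid = random_level_grid(rng)
        out = glcm_features(make_disc(grid), 1)
        assert tuple(out) == GLCM_NAMES
        for m in glcm_matrices(make_disc(grid), 1).values():
            np.testing.assert_allclose(m, m.T)

    def test_checkerboard_contrast(self):
        # strict 3D checkerboard of levels 1/2: every axial pair differs by 1
        idx = np.indices((4, 4, 4)).sum(axis=0)
        grid = (idx % 2) + 1
        out = glcm_features(make_disc(grid), 1)
        assert out["Contrast"] > 0
        assert out["MaximumProbability"] <= 1.0


class TestGLRLM:
    def test_single_run_closed_form(self):
        n = 6
        disc = make_disc(np.ones((n, 1, 1), dtype=int))
        mats = glrlm_matrices(disc)
        axis0 = mats[DIRECTIONS_13.index((1, 0, 0))]
        assert axis0.shape == (1, n)
        assert axis0[0, n - 1] == 1 and axis0.sum() == 1
        # LongRunEmphasis for that direction alone is n^2
        assert (axis0 * (np.arange(1, n + 1) ** 2)).sum() / axis0.sum() == n**2

    def test_alternating_levels_all_unit_runs(self):
        disc = make_disc(np.array([1, 2, 1, 2]).reshape(-1, 1, 1))
        axis0 = glrlm_matrices(disc)[DIRECTIONS_13.index((1, 0, 0))]
        assert axis0.shape[1] == 1  # no run longer than 1
        assert axis0.sum() == 4  # RunPercentage = 4/4 = 1 for that direction

    def test_sixteen_values(self, rng):
        out = glrlm_features(make_disc(random_level_grid(rng)))
        assert tuple(out) == GLRLM_NAMES


class TestGLSZM:
    def test_constant_region_single_zone(self):
        n = 27
        out = glszm_features(make_disc(np.ones((3, 3, 3), dtype=int)))
        assert out["ZonePercentage"] == pytest.approx(1.0 / n)
        assert out["LargeAreaEmphasis"] == pytest.approx(n**2)

    def test_two_blobs_on_background_level(self):
        grid = np.ones((6, 6, 1), dtype=int)
        grid[0, 0:3, 0] = 2  # 3-voxel zone of level 2
        grid[3:5, 3:5, 0] = 2  # 4-voxel zone
        grid[5, 0, 0] = 2
        m = glszm_matrix(make_disc(grid))
        level2_sizes = np.flatnonzero(m[1]) + 1
        assert sorted(level2_sizes) == [1, 3, 4]
        assert tuple(glszm_features(make_disc(grid))) == GLSZM_NAMES


class TestNGTDM:
    def test_hand_computed_three_voxel_row(self):
        disc = make_disc(np.array([1, 2, 1]).reshape(1, 3, 1))
        s, n = ngtdm_matrix(disc, 1)
        np.testing.assert_allclose(s, [2.0, 1.0])
        np.testing.assert_allclose(n, [2.0, 1.0])

    def test_constant_region(self):
        out = ngtdm_features(make_disc(np.ones((3, 3, 3), dtype=int)), 1)
        assert out["Contrast"] == 0.0
        assert out["Coarseness"] == 1e6  # capped: all differences vanish
        assert tuple(out) == NGTDM_NAMES


class TestGLDM:
    def test_constant_cube_center_dependence(self):
        m = gldm_matrix(make_disc(np.ones((3, 3, 3), dtype=int)), 1)
        # centre voxel: 26 equal neighbours -> j = 27; faces j = 18; edges
        # j = 12; corners j = 8
        assert m[0, 26] == 1
        assert m[0, 17] == 6
        assert m[0, 11] == 12
        assert m[0, 7] == 8
        assert m.sum() == 27

    def test_checkerboard_dependence_from_diagonals_only(self):
        idx = np.indices((4, 4, 4)).sum(axis=0)
        grid = (idx % 2) + 1
        got = gldm_matrix(make_disc(grid), 1)
        expected = brute_gldm(grid, 1)
        shape = np.maximum(got.shape, expected.shape)
        np.testing.assert_allclose(_pad_to(got, shape), _pad_to(expected, shape))
        # face neighbours always differ on a checkerboard: every dependence
        # beyond the centre itself comes from diagonal neighbours
        assert got[:, 0].sum() == 0 or got.shape[1] > 1

    def test_fourteen_values(self, rng):
        out = gldm_features(make_disc(random_level_grid(rng)), 1)
        assert tuple(out) == GLDM_NAMES
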