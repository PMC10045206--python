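"""Unit checks of the feature engine: discretization, texture toys,
first-order and shape descriptors."""

import numpy as np
import pytest

from pcatomics.features import (
    DiscretizationSpec,
    discretize,
    first_order_features,
    glcm_features,
    glcm_matrix,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    ngtdm_table,
    shape_features,
)
from pcatomics.features.texture import COARSENESS_CAP

import oracles


class TestDiscretize:
    @pytest.mark.parametrize(
        "value,n_bins,expected",
        [
            (-190.0, 8, 1),
            (-30.0, 8, 8),
            (-110.0, 16, 9),  # window midpoint, width 10 HU
            (-190.0, 32, 1),
            (-30.0, 32, 32),
        ],
    )
    def test_level_arithmetic(self, value, n_bins, expected):
        spec = DiscretizationSpec(n_bins=n_bins)
        assert discretize(np.array([value]), spec)[0] == expected

    def test_constant_input_single_level(self):
        spec = DiscretizationSpec(n_bins=16)
        levels = discretize(np.full(50, -77.3), spec)
        assert np.unique(levels).size == 1

    def test_unsupported_bin_count_rejected(self):
        with pytest.raises(ValueError):
            DiscretizationSpec(n_bins=12)


class TestGLCMToys:
    def test_uniform_patch_concentrates_at_one_cell(self):
        levels = np.ones((2, 2), dtype=int)
        mask = np.ones((2, 2), dtype=bool)
        P = glcm_matrix(levels, mask, 4)
        assert P[0, 0] == 1.0
        assert P.sum() == pytest.approx(1.0)

    def test_checkerboard_matches_pair_enumeration(self):
        levels = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 1]])
        mask = np.ones((3, 3), dtype=bool)
        P = glcm_matrix(levels, mask, 2)
        expected = oracles.glcm_matrix(levels, mask, 2)
        np.testing.assert_allclose(P, expected, rtol=0, atol=1e-15)
        # joint entropy against the direct summation
        feats = glcm_features(P)
        direct = -sum(
            p * np.log2(p) for p in P.ravel() if p > 0
        )
        assert feats["joint_entropy"] == pytest.approx(direct, rel=1e-12)

    def test_symmetry(self, rng):
        levels = rng.integers(1, 5, size=(6, 6))
        mask = rng.random((6, 6)) < 0.7
        P = glcm_matrix(levels, mask, 4)
        np.testing.assert_allclose(P, P.T, atol=1e-15)

    def test_diagonal_matrix_zero_contrast(self):
        P = np.eye(4) / 4.0
        assert glcm_features(P)["contrast"] == 0.0

    def test_uniform_matrix_energy(self):
        ng = 4
        P = np.full((ng, ng), 1.0 / ng**2)
        assert glcm_features(P)["joint_energy"] == pytest.approx(1.0 / ng**2)

    def test_single_level_conventions(self):
        levels = np.ones((3, 3), dtype=int)
        mask = np.ones((3, 3), dtype=bool)
        feats = glcm_features(glcm_matrix(levels, mask, 8))
        assert feats["correlation"] == 1.0
        assert feats["mcc"] == 1.0
        assert feats["joint_entropy"] == 0.0


class TestGLDMToys:
    def test_constant_patch_dependence(self):
        levels = np.ones((3, 3), dtype=int)
        mask = np.ones((3, 3), dtype=bool)
        counts = gldm_matrix(levels, mask, 2)
        # corner pixels have 3 equal neighbours, edges 5, centre 8
        assert counts[0, 3] == 4 and counts[0, 5] == 4 and counts[0, 8] == 1
        feats = gldm_features(counts)
        expected = oracles.gldm_features(oracles.gldm_matrix(levels, mask, 2))
        assert feats["dependence_variance"] == pytest.approx(
            expected["dependence_variance"], rel=1e-12
        )

    def test_single_pixel_mask(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        counts = gldm_matrix(np.ones((3, 3), dtype=int), mask, 2)
        assert counts.sum() == 1 and counts[0, 0] == 1

    def test_dnn_bounded(self, rng):
        levels = rng.integers(1, 4, size=(7, 7))
        mask = rng.random((7, 7)) < 0.6
        if mask.any():
            feats = gldm_features(gldm_matrix(levels, mask, 3))
            assert 0.0 < feats["dependence_non_uniformity_normalized"] <= 1.0


class TestGLRLMToys:
    def test_single_row_run(self):
        levels = np.full((1, 5), 2, dtype=int)
        mask = np.ones((1, 5), dtype=bool)
        feats = glrlm_features(levels, mask, 3)
        expected = oracles.glrlm_features(levels, mask, 3)
        for name, value in expected.items():
            assert feats[name] == pytest.approx(value, rel=1e-12), name

    def test_checkerboard_unit_runs_along_rows(self):
        """Row- and column-wise runs of a checkerboard all have length 1
        (the diagonals, by contrast, are constant)."""
        from pcatomics.features import glrlm_matrix

        levels = np.array([[1, 2, 1, 2], [2, 1, 2, 1], [1, 2, 1, 2], [2, 1, 2, 1]])
        mask = np.ones((4, 4), dtype=bool)
        horiz = glrlm_matrix(levels, mask, 2, (0, 1))
        assert horiz[:, 0].sum() == 16 and horiz[:, 1:].sum() == 0
        feats = glrlm_features(levels, mask, 2)
        expected = oracles.glrlm_features(levels, mask, 2)
        for name, value in expected.items():
            assert feats[name] == pytest.approx(value, rel=1e-12), name


class TestGLSZMToys:
    def test_uniform_patch_single_zone(self):
        levels = np.ones((4, 4), dtype=int)
        mask = np.ones((4, 4), dtype=bool)
        counts = glszm_matrix(levels, mask, 2)
        assert counts[0, 15] == 1 and counts.sum() == 1
        feats = glszm_features(levels, mask, 2)
        assert feats["zone_percentage"] == pytest.approx(1.0 / 16.0)

    def test_striped_levels_form_row_zones(self):
        """Two horizontal stripes: one zone of size 2 per level (diagonal
        contact would merge same-level zones under 8-connectivity)."""
        levels = np.array([[1, 1], [2, 2]])
        mask = np.ones((2, 2), dtype=bool)
        counts = glszm_matrix(levels, mask, 2)
        assert counts[0, 1] == 1 and counts[1, 1] == 1 and counts.sum() == 2
        feats = glszm_features(levels, mask, 2)
        assert feats["small_area_emphasis"] == pytest.approx(0.25)

    def test_zone_count_matches_flood_fill(self, rng):
        levels = rng.integers(1, 4, size=(8, 8))
        mask = rng.random((8, 8)) < 0.7
        counts = glszm_matrix(levels, mask, 3)
        assert counts.sum() == len(oracles.glszm_zones(levels, mask))


class TestNGTDMToys:
    def test_constant_patch_conventions(self):
        levels = np.full((4, 4), 3, dtype=int)
        mask = np.ones((4, 4), dtype=bool)
        feats = ngtdm_features(levels, mask, 4)
        assert feats["contrast"] == 0.0
        assert feats["coarseness"] == COARSENESS_CAP

    def test_s_column_matches_per_pixel_enumeration(self):
        levels = np.array([[1, 2, 3], [3, 1, 2], [2, 3, 1]])
        mask = np.ones((3, 3), dtype=bool)
        n_i, s_i = ngtdm_table(levels, mask, 3)
        exp_n, exp_s = oracles.ngtdm_table(levels, mask, 3)
        np.testing.assert_allclose(n_i, exp_n)
        np.testing.assert_allclose(s_i, exp_s, rtol=1e-12)

    def test_busyness_nonnegative(self, rng):
        levels = rng.integers(1, 5, size=(6, 6))
        mask = rng.random((6, 6)) < 0.8
        feats = ngtdm_features(levels, mask, 4)
        assert feats["busyness"] >= 0.0


class TestFirstOrder:
    def test_constant_input_guards(self):
        x = np.full(20, -75.0)
        levels = np.ones(20, dtype=int)
        feats = first_order_features(x, levels)
        assert feats["variance"] == 0.0
        assert feats["skewness"] == 0.0
        assert feats["kurtosis"] == 0.0
        assert feats["entropy"] == 0.0
        assert feats["uniformity"] == 1.0

    def test_small_sample_arithmetic(self):
        x = np.array([-100.0, -90.0, -80.0])
        feats = first_order_features(x, np.array([1, 2, 3]))
        assert feats["mean"] == pytest.approx(-90.0)
        assert feats["range"] == pytest.approx(20.0)
        assert feats["median"] == pytest.approx(-90.0)

    def test_uniform_histogram_uniformity(self):
        levels = np.repeat(np.arange(1, 9), 10)
        x = np.linspace(-189.0, -31.0, levels.size)
        feats = first_order_features(x, levels)
        assert feats["uniformity"] == pytest.approx(1.0 / 8.0)
        assert feats["entropy"] == pytest.approx(3.0)


class TestShape:
    def test_disc_is_nearly_circular(self):
        yy, xx = np.indices((25, 25))
        # radius 10.5 so no pixel centre sits exactly on the boundary
        mask = (yy - 12) ** 2 + (xx - 12) ** 2 <= 10.5**2
        feats = shape_features(mask, (1.0, 1.0))
        assert 0.95 <= feats["circularity"] <= 1.0
        assert feats["solidity"] == pytest.approx(1.0, abs=0.03)
        assert feats["equivalent_diameter"] == pytest.approx(21.0, abs=1.0)

    def test_rectangle_closed_forms(self):
        mask = np.zeros((30, 40), dtype=bool)
        mask[5:15, 5:25] = True  # 10 x 20 pixels
        feats = shape_features(mask, (0.5, 0.5))
        assert feats["area"] == pytest.approx(10 * 20 * 0.25, rel=1e-12)
        assert feats["perimeter"] == pytest.approx(2 * (10 + 20) * 0.5, rel=0.10)
        assert feats["bbox_height"] == pytest.approx(5.0)
        assert feats["bbox_width"] == pytest.approx(10.0)
        assert feats["extent"] == pytest.approx(1.0)
        assert feats["solidity"] == pytest.approx(1.0)

    def test_fragmented_mask_component_count(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:3, 1:3] = True
        mask[6:9, 6:9] = True
        feats = shape_features(mask, (1.0, 1.0))
        assert feats["n_components"] == 2.0

    def test_single_pixel_does_not_crash(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        feats = shape_features(mask, (0.5, 0.5))
        assert feats["area"] == pytest.approx(0.25)
        assert np.isfinite(list(feats.values())).all()

    def test_anisotropic_spacing_rejected(self):
        mask = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="isotropic"):
            shape_features(mask, (0.5, 1.0))
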