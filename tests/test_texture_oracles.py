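"""Texture families against independent brute-force enumeration oracles.

Every matrix builder is fuzzed on small grids against plain-loop pair /
run / zone / neighbor enumeration; worked micro-examples pin individual
feature values, and the conservation laws of each family are asserted.
"""

import numpy as np
import pytest

from timeradiomics.features.texture import (
    DIRECTIONS_3D,
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

import oracles
from conftest import make_droi

RTOL = 1e-9


class TestGlcm:
    def test_fuzz_matrices_match_pair_enumeration(self, fuzz_droi_suite):
        for droi in fuzz_droi_suite:
            mats = glcm_matrices(droi)
            for d, P in zip(DIRECTIONS_3D, mats):
                counts = oracles.brute_glcm(droi.levels, droi.mask, d)
                expected = np.zeros_like(P)
                for (i, j), c in counts.items():
                    expected[i - 1, j - 1] = c
                total = expected.sum()
                if total > 0:
                    expected /= total
                np.testing.assert_allclose(P, expected, rtol=RTOL, atol=1e-15)

    def test_worked_example_two_by_two(self):
        # single slice [[1,1],[1,2]], one in-plane direction, symmetric:
        # pairs {(1,1):2, (1,2):1, (2,1):1} normalized by 4
        droi = make_droi([[1, 1], [1, 2]])
        counts = oracles.brute_glcm(droi.levels, droi.mask, (0, 0, 1))
        p = {k: v / sum(counts.values()) for k, v in counts.items()}
        feats = oracles.glcm_features_from_pairs(counts)
        assert p == {(1, 1): 0.5, (1, 2): 0.25, (2, 1): 0.25}
        assert feats["JointEnergy"] == pytest.approx(0.375)
        assert feats["JointEntropy"] == pytest.approx(1.5)

    def test_selected_features_match_pair_formulas(self, fuzz_droi_suite):
        for droi in fuzz_droi_suite[:6]:
            full = glcm_features(droi)
            per_dir = {k: [] for k in
                       ("JointEnergy", "JointEntropy", "Contrast",
                        "MaximumProbability", "SumSquares")}
            for d in DIRECTIONS_3D:
                counts = oracles.brute_glcm(droi.levels, droi.mask, d)
                if not counts:  # empty direction: zero matrix convention
                    ref = dict.fromkeys(per_dir, 0.0)
                else:
                    ref = oracles.glcm_features_from_pairs(counts)
                for k in per_dir:
                    per_dir[k].append(ref[k])
            for k, vals in per_dir.items():
                assert full[k] == pytest.approx(np.mean(vals), rel=RTOL)

    def test_constant_roi_degenerate_conventions(self):
        droi = make_droi(np.ones((3, 3, 3), dtype=int))
        f = glcm_features(droi)
        assert f["MaximumProbability"] == 1.0
        assert f["Contrast"] == 0.0
        assert f["Correlation"] == 1.0
        assert f["MCC"] == 1.0
        assert f["JointEntropy"] == 0.0

    def test_matrices_normalized(self, fuzz_droi_suite):
        for droi in fuzz_droi_suite:
            for P in glcm_matrices(droi):
                if P.sum() > 0:
                    assert P.sum() == pytest.approx(1.0, rel=1e-12)


class TestGlrlm:
    def test_fuzz_matrices_match_run_enumeration(self, fuzz_droi_suite):
        for droi in fuzz_droi_suite:
            mats = glrlm_matrices(droi)
            for d, R in zip(DIRECTIONS_3D, mats):
                runs = oracles.brute_runs(droi.levels, droi.mask, d)
                expected = np.zeros_like(R)
                for g, ln in runs:
                    expected[g - 1, ln - 1] += 1
                np.testing.assert_allclose(R, expected, rtol=RTOL)

    def test_worked_example_short_run_emphasis(self):
        droi = make_droi([1, 1, 2])
        runs = oracles.brute_runs(droi.levels, droi.mask, (0, 0, 1))
        assert sorted(runs) == [(1, 2), (2, 1)]
        sre = sum(1.0 / ln**2 for _g, ln in runs) / len(runs)
        assert sre == pytest.approx(0.625)
        (R,) = glrlm_matrices(droi, directions=[(0, 0, 1)])
        assert R[0, 1] == 1 and R[1, 0] == 1

    def test_constant_roi_single_direction_run_percentage(self):
        droi = make_droi(np.ones((1, 1, 6), dtype=int))
        mats = glrlm_matrices(droi, directions=[(0, 0, 1)])
        assert mats[0].sum() == 1  # exactly one run
        from timeradiomics.features.texture import _rlm_style_features

        f = _rlm_style_features(mats[0], droi.n_voxels, "run")
        assert f["RunPercentage"] == pytest.approx(1.0 / 6.0)

    def test_run_length_conservation(self, fuzz_droi_suite):
        for droi in fuzz_droi_suite:
            n = droi.n_voxels
            for R in glrlm_matrices(droi):
                lengths = np.arange(1, R.shape[1] + 1)
                assert (R * lengths).sum() == pytest.approx(n)

    def test_selected_features_match_run_formulas(self, fuzz_droi_suite):
        for droi in fuzz_droi_suite[:6]:
            full = glrlm_features(droi)
            acc = {k: [] for k in ("ShortRunEmphasis", "GrayLevelNonUniformity",
                                   "RunPercentage", "HighGrayLevelRunEmphasis")}
            for d in DIRECTIONS_3D:
                runs = oracles.brute_runs(droi.levels, droi.mask, d)
                ref = oracles.rlm_features_from_sizes(
                    runs, droi.n_voxels, "ShortRunEmphasis", "Run"
                )
                acc["ShortRunEmphasis"].append(ref["ShortRunEmphasis"])
                acc["GrayLevelNonUniformity"].append(ref["GrayLevelNonUniformity"])
                acc["RunPercentage"].append(ref["Percentage"])
                acc["HighGrayLevelRunEmphasis"].append(ref["HighGrayLevel"])
            for k, vals in acc.items():
                assert full[k] == pytest.approx(np.mean(vals), rel=RTOL)


class TestGlszm:
    def test_fuzz_matrix_matches_zone_enumeration(self, fuzz_droi_suite):
        for droi in fuzz_droi_suite:
            Z = glszm_matrix(droi)
            zones = oracles.brute_zones(droi.levels, droi.mask)
            expected = np.zeros_like(Z)
            for g, s in zones:
                expected[g - 1, s - 1] += 1
            np.testing.assert_allclose(Z, expected, rtol=RTOL)

    def test_worked_example_size_zone_nonuniformity(self):
        droi = make_droi([1, 1, 2])
        zones = oracles.brute_zones(droi.levels, droi.mask)
        assert sorted(zones) == [(1, 2), (2, 1)]
        f = glszm_features(droi)
        assert f["SizeZoneNonUniformity"] == pytest.approx(1.0)

    def test_constant_roi_zone_percentage(self):
        droi = make_droi(np.ones((2, 3, 4), dtype=int))
        f = glszm_features(droi)
        assert f["ZonePercentage"] == pytest.approx(1.0 / 24.0)

    def test_zone_size_conservation(self, fuzz_droi_suite):
        for droi in fuzz_droi_suite:
            Z = glszm_matrix(droi)
            sizes = np.arange(1, Z.shape[1] + 1)
            assert (Z * sizes).sum() == pytest.approx(droi.n_voxels)


class TestNgtdm:
    def test_fuzz_table_matches_neighbor_loops(self, fuzz_droi_suite):
        for droi in fuzz_droi_suite:
            tab = ngtdm_matrix(droi)
            n_ref, s_ref = oracles.brute_ngtdm(droi.levels, droi.mask)
            for g in range(1, droi.ng + 1):
                assert tab[g - 1, 0] == pytest.approx(n_ref.get(g, 0))
                np.testing.assert_allclose(
                    tab[g - 1, 2], s_ref.get(g, 0.0), rtol=RTOL, atol=1e-12
                )

    def test_constant_roi_contrast_complexity_zero(self):
        droi = make_droi(np.ones((3, 3, 3), dtype=int))
        f = ngtdm_features(droi)
        assert f["Contrast"] == 0.0
        assert f["Complexity"] == 0.0
        assert f["Coarseness"] == 1e6  # capped, not infinite

    def test_checkerboard_slice_neighbor_differences(self):
        levels = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 1]])
        droi = make_droi(levels)
        n_ref, s_ref = oracles.brute_ngtdm(droi.levels, droi.mask)
        tab = ngtdm_matrix(droi)
        # corner level-1 voxels have neighbors {2,2,1}: diff = |1 - 5/3|
        assert n_ref[1] == 5 and n_ref[2] == 4
        np.testing.assert_allclose(tab[0, 2], s_ref[1], rtol=RTOL)
        np.testing.assert_allclose(tab[1, 2], s_ref[2], rtol=RTOL)
        ref = oracles.ngtdm_features_from_table(n_ref, s_ref)
        f = ngtdm_features(droi)
        assert f["Coarseness"] == pytest.approx(ref["Coarseness"], rel=RTOL)
        assert f["Contrast"] == pytest.approx(ref["Contrast"], rel=RTOL)

    def test_level_shift_invariance(self, fuzz_droi_suite):
        for droi in fuzz_droi_suite[:4]:
            shifted = make_droi(droi.levels + 2 * droi.mask, mask=droi.mask)
            a = ngtdm_features(droi)
            b = ngtdm_features(shifted)
            for name in ("Contrast", "Coarseness", "Complexity"):
                assert a[name] == pytest.approx(b[name], rel=1e-6)


class TestGldm:
    def test_fuzz_matrix_matches_neighbor_census(self, fuzz_droi_suite):
        for droi in fuzz_droi_suite:
            P = gldm_matrix(droi, alpha=0)
            counts = oracles.brute_gldm(droi.levels, droi.mask, alpha=0)
            expected = np.zeros_like(P)
            for (g, d), c in counts.items():
                expected[g - 1, d] += c
            np.testing.assert_allclose(P, expected, rtol=RTOL)

    def test_constant_cube_dependence_counts(self):
        droi = make_droi(np.ones((3, 3, 3), dtype=int))
        counts = oracles.brute_gldm(droi.levels, droi.mask, alpha=0)
        assert counts[(1, 26)] == 1  # center voxel: all 26 neighbors agree
        assert counts[(1, 7)] == 8  # corners
        ref = oracles.gldm_features_from_counts(counts)
        f = gldm_features(droi, alpha=0)
        assert f["DependenceNonUniformityNormalized"] == pytest.approx(
            ref["DependenceNonUniformityNormalized"], rel=RTOL
        )

    def test_single_voxel_dependence_zero_column(self):
        droi = make_droi([[7]])
        P = gldm_matrix(droi)
        assert P.shape[1] == 1 and P[6, 0] == 1

    def test_voxel_count_conservation(self, fuzz_droi_suite):
        for droi in fuzz_droi_suite:
            assert gldm_matrix(droi).sum() == droi.n_voxels
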