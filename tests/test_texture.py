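"""Texture matrices against brute-force oracles, plus discretisation."""

import numpy as np
import pytest

from conftest import brute_glcm, brute_glrlm, brute_glszm, random_levels
from noderad.texture import (
    discretize_fixed_count,
    discretize_fixed_width,
    extract_texture,
    glcm_features,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_features,
    ngtdm_table,
)


# ---------------------------------------------------------------------------
# discretisation

def test_fixed_width_anchor_and_top_edge():
    img = np.array([[[-20.0, 180.0, 0.0, 57.5]]])
    valid = np.ones(img.shape, bool)
    lv = discretize_fixed_width(img, valid, 5.0, -20.0)
    assert lv[0, 0, 0] == 1          # anchor value -> first bin
    assert lv[0, 0, 1] == 40         # top edge assigned to the last bin
    assert lv[0, 0, 2] == 5          # floor((0+20)/5)+1
    assert lv[0, 0, 3] == 16


def test_uniform_ramp_fills_bins_evenly():
    img = np.linspace(-20, 180, 4000).reshape(10, 20, 20)
    valid = np.ones(img.shape, bool)
    lv = discretize_fixed_width(img, valid, 5.0, -20.0)
    counts = np.bincount(lv.ravel())[1:]
    assert len(counts) == 40
    assert counts.min() >= 0.9 * counts.max()


@pytest.mark.parametrize("width", [10.0, 5.0, 2.5])
def test_halving_bin_width_never_loses_levels(width):
    rng = np.random.default_rng(4)
    img = rng.uniform(-20, 180, size=(6, 6, 6))
    valid = rng.random(img.shape) < 0.8
    coarse = len(np.unique(discretize_fixed_width(img, valid, width, -20.0)[valid]))
    fine = len(np.unique(discretize_fixed_width(img, valid, width / 2, -20.0)[valid]))
    assert fine >= coarse


def test_fixed_count_constant_input():
    img = np.full((3, 3, 3), 7.0)
    valid = np.ones(img.shape, bool)
    lv = discretize_fixed_count(img, valid, 40)
    assert (lv[valid] == 1).all()


# ---------------------------------------------------------------------------
# degenerate and hand-computable cases

def test_constant_roi_entropy_and_complexity_are_zero():
    levels = np.ones((4, 4, 4), dtype=np.int64)
    valid = np.ones((4, 4, 4), bool)
    feats = extract_texture(levels, valid)
    assert feats["glcm_entropy"] == 0.0
    assert feats["ngtdm_complexity"] == 0.0
    assert feats["glcm_asm"] == 1.0
    assert feats["glszm_zone_entropy"] == 0.0


def test_checkerboard_glcm_by_hand():
    """2x2x1 checkerboard of levels {1,2}: in-plane neighbours always
    differ, the single diagonal pair matches."""
    levels = np.array([[[1], [2]], [[2], [1]]])
    valid = np.ones(levels.shape, bool)
    p = glcm_matrix(levels, valid)
    np.testing.assert_allclose(p, brute_glcm(levels, valid), atol=1e-12)
    # direction (0,0,1) etc. contribute nothing; axis pairs are (1,2)/(2,1),
    # the two in-plane diagonals are (1,1) and (2,2)
    feats = glcm_features(p)
    assert feats["glcm_joint_max"] <= 1.0
    ent_oracle = -(p[p > 0] * np.log2(p[p > 0])).sum()
    assert feats["glcm_entropy"] == pytest.approx(ent_oracle, abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_glcm_matches_bruteforce(seed):
    levels, valid = random_levels((4, 4, 4), 3, seed, p_valid=0.85)
    if not valid.any():
        pytest.skip("empty fixture")
    np.testing.assert_allclose(
        glcm_matrix(levels, valid), brute_glcm(levels, valid), atol=1e-12
    )


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_glrlm_matches_bruteforce(seed):
    levels, valid = random_levels((4, 4, 4), 3, seed, p_valid=0.85)
    r = glrlm_matrix(levels, valid)
    b = brute_glrlm(levels, valid)
    assert r.shape == b.shape
    np.testing.assert_allclose(r, b, atol=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_glszm_matches_bruteforce(seed):
    levels, valid = random_levels((4, 4, 4), 3, seed, p_valid=0.85)
    m = glszm_matrix(levels, valid)
    b = brute_glszm(levels, valid)
    assert m.shape == b.shape
    np.testing.assert_allclose(m, b, atol=1e-12)


def test_glszm_zone_sizes_partition_roi():
    levels, valid = random_levels((6, 5, 4), 4, seed=9, p_valid=0.7)
    m = glszm_matrix(levels, valid)
    sizes = np.arange(1, m.shape[1] + 1)
    assert (m @ sizes).sum() == valid.sum()


def test_ngtdm_two_level_hand_case():
    """Alternating columns of 1 and 2: every voxel's neighbour average is
    computable by hand through the oracle table."""
    levels = np.tile(np.array([[[1, 2, 1, 2]]]), (3, 3, 1))
    valid = np.ones(levels.shape, bool)
    p, s, n = ngtdm_table(levels, valid)
    assert n == levels.size
    assert p.sum() == pytest.approx(1.0)
    feats = ngtdm_features(p, s, n)
    assert feats["ngtdm_contrast"] > 0
    assert feats["ngtdm_coarseness"] == pytest.approx(1.0 / (p * s).sum())


def test_texture_invariant_under_axis_rotations():
    levels, valid = random_levels((5, 5, 5), 4, seed=11, p_valid=0.9)
    ref = extract_texture(levels, valid)
    for axes in ((0, 1), (0, 2), (1, 2)):
        rot = extract_texture(
            np.rot90(levels, k=1, axes=axes), np.rot90(valid, k=1, axes=axes)
        )
        for key, val in ref.items():
            assert rot[key] == pytest.approx(val, rel=1e-9), key


def test_single_voxel_degenerate_substitution():
    levels = np.zeros((3, 3, 3), dtype=np.int64)
    valid = np.zeros((3, 3, 3), bool)
    levels[1, 1, 1] = 5
    valid[1, 1, 1] = True
    feats = extract_texture(levels, valid)
    assert all(np.isfinite(v) for v in feats.values())
    assert feats["glcm_entropy"] == 0.0
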