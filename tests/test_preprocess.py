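"""Artifact handling, eligibility, resampling, windowing, LN merging."""

import numpy as np
import pytest

from conftest import make_ball, make_volume
from noderad.datatypes import EmptyROIError
from noderad.preprocess import (
    PreprocessConfig,
    check_eligibility,
    merge_ln,
    remove_artifact_slices,
    resample,
    window_hu,
)

CFG = PreprocessConfig()


def _simple_volume(artifact_slices=(), pt=None, ln=None, spacing=(1.0, 1.0, 1.0)):
    shape = (20, 20, 20)
    img = np.full(shape, 50.0)
    if pt is None:
        pt = np.zeros(shape, bool)
        pt[5:10, 5:10, 5:10] = True
    if ln is None:
        ln = np.zeros(shape, bool)
        ln[14:17, 14:17, 14:17] = True
    return make_volume(img, pt, ln, spacing=spacing,
                       artifact_slices=frozenset(artifact_slices))


def test_remove_artifact_slices_noop_and_count():
    v = _simple_volume()
    assert np.array_equal(remove_artifact_slices(v).pt_mask, v.pt_mask)

    # 100-voxel mask with 30 voxels on a listed slice -> 70 remain
    pt = np.zeros((20, 20, 20), bool)
    pt[4, :10, :5] = True          # 50 voxels on slice 4
    pt[5, :10, :5] = True          # 50 voxels on slice 5
    pt[4, 15, :10] = False
    v = _simple_volume(artifact_slices=[4], pt=pt)
    n_on_slice = int(pt[4].sum())
    out = remove_artifact_slices(v)
    assert out.pt_mask.sum() == pt.sum() - n_on_slice
    assert np.array_equal(out.image, v.image)  # image untouched


def test_remove_all_pt_slices_empties_mask():
    v = _simple_volume(artifact_slices=range(5, 10))
    assert not remove_artifact_slices(v).pt_mask.any()


def _fraction_volume(n_on_artifact, total=100):
    """Combined ROI of ``total`` voxels with ``n_on_artifact`` on slice 0."""
    pt = np.zeros((20, 20, 20), bool)
    pt[0].flat[:n_on_artifact] = True
    pt[5].flat[: total - n_on_artifact] = True
    ln = np.zeros((20, 20, 20), bool)
    return make_volume(np.zeros((20, 20, 20)), pt, ln,
                       artifact_slices=frozenset([0]))


@pytest.mark.parametrize(
    "n_bad,expected", [(0, True), (40, True), (50, False), (80, False)]
)
def test_eligibility_rule_is_strict_less_than(n_bad, expected):
    """Exactly half the ROI on artifact slices is already ineligible."""
    assert check_eligibility(_fraction_volume(n_bad), CFG) is expected


def test_eligibility_empty_roi_raises():
    shape = (10, 10, 10)
    v = make_volume(np.zeros(shape), np.zeros(shape, bool), np.zeros(shape, bool))
    with pytest.raises(EmptyROIError):
        check_eligibility(v, CFG)


def test_eligibility_monotone_in_artifact_slices():
    base = _simple_volume(artifact_slices=[5, 6])
    was_eligible = check_eligibility(base, CFG)
    more = _simple_volume(artifact_slices=[5, 6, 7, 8])
    if not was_eligible:
        assert check_eligibility(more, CFG) is False


def test_resample_identity_at_target_spacing():
    v = _simple_volume(spacing=(3.3, 3.3, 3.3))
    out = resample(v, CFG)
    assert out.spacing == (3.3, 3.3, 3.3)
    assert out.image.shape == v.image.shape
    np.testing.assert_allclose(out.image, v.image, atol=1e-9)


def test_resample_sphere_volume_conserved():
    r = 12
    mask = make_ball(r, pad=3)
    img = np.where(mask, 60.0, 20.0)
    v = make_volume(img, mask, _one_ln_far(mask.shape))
    out = resample(v, CFG)
    vol_before = mask.sum() * 1.0
    vol_after = out.pt_mask.sum() * 3.3**3
    assert abs(vol_after - vol_before) / vol_before < 0.15


def _one_ln_far(shape):
    ln = np.zeros(shape, bool)
    ln[-3:, -3:, -3:] = True
    return ln


def test_resample_anisotropic_extent_preserved():
    """Typical planning-CT grid (0.98 x 0.98 mm in-plane, 2 mm slices)."""
    v = _simple_volume(spacing=(2.0, 0.98, 0.98))
    out = resample(v, CFG)
    for ax in range(3):
        before = v.image.shape[ax] * v.spacing[ax]
        after = out.image.shape[ax] * 3.3
        assert abs(after - before) <= 3.3  # within one voxel per axis


def test_window_closed_interval_and_exclusion():
    shape = (8, 8, 8)
    img = np.full(shape, 1000.0)
    img[0] = -20.0
    img[1] = 180.0
    img[2] = 50.0
    pt = np.zeros(shape, bool)
    pt[:4] = True
    v = make_volume(img, pt, _one_ln_far(shape))
    out = window_hu(v, CFG)
    assert out.pt_valid[0].all() and out.pt_valid[1].all()  # boundaries included
    assert not out.pt_valid[3].any()                        # 1000 HU excluded
    assert np.array_equal(out.pt_mask, v.pt_mask)           # mask untouched
    # intensity over the remainder only
    vals = out.image[out.pt_valid]
    assert vals.max() <= 180.0 and vals.min() >= -20.0


def test_merge_ln_counts_components():
    shape = (20, 20, 20)
    ln = np.zeros(shape, bool)
    ln[1:2, 1:6, 1:3] = True        # 10 voxels
    ln[5:7, 5:10, 5:7] = True       # 20 voxels
    ln[10:13, 10:15, 10:12] = True  # 30 voxels
    v = make_volume(np.zeros(shape), _pt_block(shape), ln)
    out = merge_ln(v)
    assert out.ln_mask.sum() == 60
    assert out.ln_labels.max() == 3


def test_merge_ln_face_touching_components_join():
    shape = (10, 10, 10)
    ln = np.zeros(shape, bool)
    ln[2:4, 2:4, 2:4] = True
    ln[4:6, 2:4, 2:4] = True  # touches face-to-face
    v = make_volume(np.zeros(shape), _pt_block(shape), ln)
    assert merge_ln(v).ln_labels.max() == 1


def _pt_block(shape):
    pt = np.zeros(shape, bool)
    pt[-2:, -2:, -2:] = True
    return pt
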