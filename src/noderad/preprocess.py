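"""ROI preparation: artifact handling, resampling, HU windowing, LN merging.

The preparation chain mirrors standard CT radiomics practice for head-and-
neck cohorts with metal artifacts: patients keep their ROIs only where no
streak artifacts are present (contours on artifact slices are removed), and
a patient is eligible only if strictly less than half of the ROI volume sat
on artifact slices.  Images are then resampled to cubic voxels (3.3 mm by
default, a typical coarsest planning-CT resolution), all LN components are
merged into a single ROI, and a soft-tissue Hounsfield window of
[-20, 180] HU marks the voxels admitted to intensity/texture analysis.
Out-of-window voxels are excluded, not clamped; shape features always use
the full mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .datatypes import EmptyROIError, VolumeWithMasks

log = logging.getLogger(__name__)

# 26-connectivity for LN component labelling
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class PreprocessConfig:
    target_spacing: float = 3.3          # mm, cubic
    hu_window: tuple[float, float] = (-20.0, 180.0)
    artifact_volume_limit: float = 0.5   # strict "less than" rule
    mask_threshold: float = 0.5          # re-binarisation after resampling
    per_roi_eligibility: bool = False    # evaluate PT and LN separately
    window_before_resample: bool = False

    def __post_init__(self):
        if self.hu_window[0] >= self.hu_window[1]:
            raise ValueError("hu_window lower bound must be below upper bound")
        if not (0 < self.artifact_volume_limit <= 1):
            raise ValueError("artifact_volume_limit must be in (0, 1]")
        if self.target_spacing <= 0:
            raise ValueError("target_spacing must be positive")


def check_eligibility(v: VolumeWithMasks, cfg: PreprocessConfig) -> bool:
    """Apply the artifact-volume eligibility rule on the original masks.

    A patient is eligible iff the ROI volume lying on artifact slices is
    strictly less than ``artifact_volume_limit`` (default 50%) of the total
    ROI volume.  By default the rule is evaluated on the combined PT u LN
    region; set ``per_roi_eligibility`` to require it of each ROI.
    """

    def _fraction(mask: np.ndarray) -> float:
        total = int(mask.sum())
        if total == 0:
            raise EmptyROIError(f"{v.patient_id}: empty ROI in eligibility check")
        if not v.artifact_slices:
            return 0.0
        idx = sorted(v.artifact_slices)
        return float(mask[idx].sum()) / total

    if cfg.per_roi_eligibility:
        fr = max(_fraction(v.pt_mask), _fraction(v.ln_mask))
    else:
        fr = _fraction(v.pt_mask | v.ln_mask)
    ok = fr < cfg.artifact_volume_limit
    log.info("%s: artifact ROI fraction %.3f -> eligible=%s", v.patient_id, fr, ok)
    return ok


def remove_artifact_slices(v: VolumeWithMasks) -> VolumeWithMasks:
    """Zero mask voxels on artifact slices; image values are untouched."""
    if not v.artifact_slices:
        return v.copy()
    out = v.copy()
    idx = sorted(v.artifact_slices)
    out.pt_mask[idx] = False
    out.ln_mask[idx] = False
    return out


def _resample_array(
    arr: np.ndarray,
    spacing: tuple[float, float, float],
    target: float,
    interpolator,
    new_shape: tuple[int, int, int],
) -> np.ndarray:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr, dtype=np.float64))
    img.SetSpacing(tuple(spacing[::-1]))  # sitk spacing is (x, y, z)
    out = sitk.Resample(
        img,
        tuple(int(n) for n in new_shape[::-1]),
        sitk.Transform(),
        interpolator,
        (0.0, 0.0, 0.0),
        (target, target, target),
        img.GetDirection(),
        0.0,
        sitk.sitkFloat64,
    )
    return sitk.GetArrayFromImage(out)


def resample(v: VolumeWithMasks, cfg: PreprocessConfig) -> VolumeWithMasks:
    """Resample image and masks to cubic voxels of ``target_spacing`` mm.

    The image is interpolated tri-linearly; masks are interpolated
    tri-linearly and re-binarised at ``mask_threshold``.  The physical
    extent of the grid is preserved to within one voxel per axis.
    """
    t = cfg.target_spacing
    new_shape = tuple(
        max(1, int(np.ceil(n * s / t))) for n, s in zip(v.image.shape, v.spacing)
    )
    if any(n <= 0 for n in new_shape):
        raise ValueError("resampling produced a zero-size grid")
    image = _resample_array(v.image, v.spacing, t, sitk.sitkLinear, new_shape)
    def _mask(m):
        if m is None:
            return None
        f = _resample_array(m.astype(np.float64), v.spacing, t, sitk.sitkLinear, new_shape)
        return f > cfg.mask_threshold

    return v.copy(
        image=image,
        spacing=(t, t, t),
        pt_mask=_mask(v.pt_mask),
        ln_mask=_mask(v.ln_mask),
        artifact_slices=frozenset(),  # slice bookkeeping is void on the new grid
        ln_labels=None,
        pt_valid=_mask(v.pt_valid),
        ln_valid=_mask(v.ln_valid),
    )


def window_hu(v: VolumeWithMasks, cfg: PreprocessConfig) -> VolumeWithMasks:
    """Mark in-window ROI voxels for intensity/texture analysis.

    The window is a closed interval; voxels outside it are excluded from
    first-order and texture analysis but remain part of the mask used for
    shape features.
    """
    lo, hi = cfg.hu_window
    in_window = (v.image >= lo) & (v.image <= hi)
    return v.copy(pt_valid=v.pt_mask & in_window, ln_valid=v.ln_mask & in_window)


def merge_ln(v: VolumeWithMasks) -> VolumeWithMasks:
    """Merge all LN components into one ROI, retaining component labels.

    Components are identified with 26-connectivity; the merged ROI is the
    plain union (the mask is unchanged), while ``ln_labels`` records which
    voxel belongs to which node for the spatial-distribution features.
    """
    labels, n = ndimage.label(v.ln_mask, structure=_STRUCT_26)
    log.debug("%s: %d LN component(s)", v.patient_id, n)
    return v.copy(ln_labels=labels)


def preprocess_patient(v: VolumeWithMasks, cfg: PreprocessConfig) -> VolumeWithMasks:
    """Run the full preparation chain on one patient.

    Order: eligibility check (on original masks), artifact-slice removal,
    resampling, LN merging, HU windowing.  Raises ``EmptyROIError`` if a
    ROI vanishes along the way; sets ``eligible`` on the returned object.
    """
    eligible = check_eligibility(v, cfg)
    out = remove_artifact_slices(v)
    if not out.pt_mask.any() or not out.ln_mask.any():
        raise EmptyROIError(f"{v.patient_id}: ROI fully removed with artifact slices")
    if cfg.window_before_resample:
        out = window_hu(out, cfg)
    out = resample(out, cfg)
    if not out.pt_mask.any() or not out.ln_mask.any():
        raise EmptyROIError(f"{v.patient_id}: ROI lost in resampling")
    out = merge_ln(out)
    if not cfg.window_before_resample:
        out = window_hu(out, cfg)
    out.eligible = eligible
    return out
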