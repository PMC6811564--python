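"""Per-ROI extraction of the full 285-feature panel.

For each ROI the panel is: 18 shape features on the full mask, 17 intensity
and 72 texture features on the HU-windowed voxels of the original image,
and the same 89 intensity+texture features recomputed on the LLL and HHH
stationary-wavelet subbands (178 wavelet features).  The original image is
discretised with a fixed bin width anchored at the HU window floor; wavelet
subbands, whose scale is not anchored to HU, use a fixed bin count over
their own in-ROI range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import EmptyROIError, VolumeWithMasks
from .intensity import extract_intensity
from .manifest import DEFAULT_MANIFEST, FeatureManifest
from .shape import extract_shape
from .texture import discretize_fixed_count, discretize_fixed_width, extract_texture
from .wavelet import wavelet_maps


@dataclass
class FeatureVector:
    roi_id: str
    group: str  # "PT" or "LN"
    values: dict[str, float]

    def __len__(self) -> int:
        return len(self.values)


def extract_roi(
    image: np.ndarray,
    mask: np.ndarray,
    valid: np.ndarray,
    spacing,
    manifest: FeatureManifest = DEFAULT_MANIFEST,
    hu_anchor: float = -20.0,
) -> dict[str, float]:
    """Extract all 285 features for one ROI."""
    if not mask.any():
        raise EmptyROIError("empty ROI mask")
    if int(valid.sum()) < 2:
        raise EmptyROIError("fewer than 2 in-window ROI voxels")

    out = dict(extract_shape(mask, spacing, image=image))

    levels = discretize_fixed_width(image, valid, manifest.bin_width, hu_anchor)
    out.update(extract_intensity(image[valid], levels[valid]))
    out.update(extract_texture(levels, valid))

    maps = wavelet_maps(image, valid, wavelet=manifest.wavelet)
    for sb in manifest.wavelet_subbands:
        sub = maps[sb]
        sub_levels = discretize_fixed_count(sub, valid, manifest.subband_bins)
        sub_int = extract_intensity(sub[valid], sub_levels[valid])
        sub_tex = extract_texture(sub_levels, valid)
        for name, val in {**sub_int, **sub_tex}.items():
            out[f"{name}_{sb}"] = val

    ordered = {name: float(out[name]) for name in manifest.all_names}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad[:5]}")
    return ordered


def extract_all(
    v: VolumeWithMasks, manifest: FeatureManifest = DEFAULT_MANIFEST
) -> tuple[FeatureVector, FeatureVector]:
    """Extract the PT and LN feature vectors of one preprocessed patient."""
    if v.pt_valid is None or v.ln_valid is None:
        raise ValueError("patient must be HU-windowed before extraction")
    pt = extract_roi(v.image, v.pt_mask, v.pt_valid, v.spacing, manifest)
    ln = extract_roi(v.image, v.ln_mask, v.ln_valid, v.spacing, manifest)
    return (
        FeatureVector(v.patient_id, "PT", pt),
        FeatureVector(v.patient_id, "LN", ln),
    )


def cohort_feature_matrix(
    patients: list[VolumeWithMasks],
    manifest: FeatureManifest = DEFAULT_MANIFEST,
    include_lnpt: bool = True,
) -> pd.DataFrame:
    """Patients x features table with ``pt_``/``ln_``/``lnpt_`` prefixes."""
    from .lnpt import extract_lnpt, structure_set_from_volume

    rows = {}
    for v in patients:
        pt, ln = extract_all(v, manifest)
        row = {f"pt_{k}": val for k, val in pt.values.items()}
        row.update({f"ln_{k}": val for k, val in ln.values.items()})
        if include_lnpt:
            row.update(extract_lnpt(structure_set_from_volume(v)))
        rows[v.patient_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df


def feature_group(df: pd.DataFrame, group: str) -> pd.DataFrame:
    """Slice a cohort matrix to one feature group ('PT', 'LN' or 'LNPT')."""
    prefix = {"PT": "pt_", "LN": "ln_", "LNPT": "lnpt_"}[group]
    cols = [c for c in df.columns if c.startswith(prefix)]
    return df[cols]
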