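"""First-order intensity statistics over in-window ROI voxels."""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .datatypes import EmptyROIError

log = logging.getLogger(__name__)


def histogram_entropy(levels: np.ndarray) -> float:
    """Shannon entropy (bits) of the discretised grey-level histogram."""
    counts = np.bincount(np.asarray(levels, dtype=np.int64))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def extract_intensity(values: np.ndarray, levels: np.ndarray) -> dict[str, float]:
    """Compute the 17 first-order features.

    ``values`` are the raw in-window ROI intensities; ``levels`` are the
    same voxels after discretisation, used only for the histogram entropy.
    A constant ROI has no defined skewness/kurtosis; both are substituted
    with 0 and the substitution is logged.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise EmptyROIError("intensity features need at least 2 valid voxels")
    mean = v.mean()
    sd = v.std()
    if sd > 0:
        skew = float(stats.skew(v))
        kurt = float(stats.kurtosis(v, fisher=False))
    else:
        log.debug("constant ROI: skewness/kurtosis substituted with 0")
        skew = kurt = 0.0
    p10, q1, med, q3, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    return {
        "intensity_mean": float(mean),
        "intensity_variance": float(v.var()),
        "intensity_sd": float(sd),
        "intensity_skewness": skew,
        "intensity_kurtosis": kurt,
        "intensity_median": float(med),
        "intensity_min": float(v.min()),
        "intensity_max": float(v.max()),
        "intensity_range": float(v.max() - v.min()),
        "intensity_p10": float(p10),
        "intensity_p90": float(p90),
        "intensity_iqr": float(q3 - q1),
        "intensity_mad": float(np.abs(v - mean).mean()),
        "intensity_robust_mad": float(np.abs(robust - robust.mean()).mean())
        if robust.size
        else 0.0,
        "intensity_energy": float((v**2).sum()),
        "intensity_rms": float(np.sqrt((v**2).mean())),
        "intensity_histogram_entropy": histogram_entropy(levels),
    }
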