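"""One-level 3-D stationary wavelet maps (LLL and HHH subbands).

The undecimated transform keeps the subbands on the original voxel lattice,
so ROI masks apply unchanged.  The default kernel is Haar, whose low-pass
branch has DC gain sqrt(2) per axis (2^(3/2) in 3-D) and whose high-pass
branch annihilates constants exactly.  The transform runs on the ROI
bounding box (padded to even side lengths as required by the stationary
transform) and the result is placed back onto the full lattice.
"""

from __future__ import annotations

import numpy as np
import pywt


def haar_dc_gain(ndim: int = 3, wavelet: str = "haar") -> float:
    """DC gain of the all-low-pass branch of the separable transform."""
    w = pywt.Wavelet(wavelet)
    return float(np.sum(w.dec_lo)) ** ndim


def wavelet_maps(
    image: np.ndarray, valid_mask: np.ndarray, wavelet: str = "haar"
) -> dict[str, np.ndarray]:
    """Return {'lll': grid, 'hhh': grid} on the original lattice.

    Computed over the bounding box of ``valid_mask``; voxels outside the
    box are 0 in the returned maps.  Raises ``ValueError`` naming the axis
    if the box is thinner than the filter support along some axis.
    """
    if not valid_mask.any():
        raise ValueError("wavelet_maps needs a non-empty ROI")
    w = pywt.Wavelet(wavelet)
    support = len(w.dec_lo)
    idx = np.argwhere(valid_mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    for ax in range(3):
        if hi[ax] - lo[ax] < support:
            # widen within the grid if possible, else refuse
            need = support - (hi[ax] - lo[ax])
            lo[ax] = max(0, lo[ax] - need)
            hi[ax] = min(image.shape[ax], hi[ax] + need)
            if hi[ax] - lo[ax] < support:
                raise ValueError(
                    f"ROI thinner than the {wavelet} filter support along axis {ax}"
                )
    box = image[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.float64)
    pad = [(0, (2 - s % 2) % 2) for s in box.shape]  # swt needs even lengths
    padded = np.pad(box, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    out = {}
    for name, key in (("lll", "aaa"), ("hhh", "ddd")):
        full = np.zeros(image.shape, dtype=np.float64)
        sub = coeffs[key][: box.shape[0], : box.shape[1], : box.shape[2]]
        full[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
        out[name] = full
    return out
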