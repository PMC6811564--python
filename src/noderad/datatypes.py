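"""Shared data containers.

Array convention
----------------
All image and mask grids are indexed ``(z, y, x)``: axis 0 is the axial
(slice) axis, and ``spacing`` gives millimetres per grid step in the same
axis order.  Physical positions are ``index * spacing`` (the origin is the
centre of voxel ``(0, 0, 0)``); all distances are in millimetres in this
physical frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


class EmptyROIError(ValueError):
    """Raised when an operation requires a non-empty region of interest."""


@dataclass
class VolumeWithMasks:
    """One patient's CT grid with primary-tumour and lymph-node masks.

    ``pt_valid`` / ``ln_valid`` mark the in-window ROI voxels used for
    intensity and texture analysis; they are ``None`` until HU windowing
    has run.  ``ln_labels`` holds per-component integer labels of the LN
    mask (0 = background), retained for the spatial-distribution features
    after the components are merged into one ROI.
    """

    patient_id: str
    image: np.ndarray
    spacing: tuple[float, float, float]
    pt_mask: np.ndarray
    ln_mask: np.ndarray
    artifact_slices: frozenset[int] = field(default_factory=frozenset)
    eligible: Optional[bool] = None
    ln_labels: Optional[np.ndarray] = None
    pt_valid: Optional[np.ndarray] = None
    ln_valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.pt_mask = np.asarray(self.pt_mask, dtype=bool)
        self.ln_mask = np.asarray(self.ln_mask, dtype=bool)
        if self.image.ndim != 3:
            raise ValueError("image must be a 3-D grid")
        if self.pt_mask.shape != self.image.shape or self.ln_mask.shape != self.image.shape:
            raise ValueError("image and masks must share one grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive lengths (mm)")
        self.artifact_slices = frozenset(int(s) for s in self.artifact_slices)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def copy(self, **changes) -> "VolumeWithMasks":
        out = replace(self, **changes)
        for name in ("image", "pt_mask", "ln_mask", "ln_labels", "pt_valid", "ln_valid"):
            val = getattr(out, name)
            if val is not None and val is getattr(self, name, None):
                setattr(out, name, val.copy())
        return out


def derive_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from a global seed.

    Uses a small string hash so independent pipeline stages draw from
    decorrelated streams while the whole run stays reproducible from one
    integer.
    """
    import hashlib

    h = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)
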