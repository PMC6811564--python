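"""Synthetic phantom cohorts with known ground truth.

Real contrast-CT cohorts for head-and-neck radiomics are rarely shareable,
so every downstream stage of this package is exercised on phantoms: each
patient is a 3-D grid holding one primary-tumour (PT) blob and one to five
lymph-node (LN) blobs with soft-tissue-like Hounsfield values, plus linked
survival outcomes drawn from a proportional-hazards model whose linear
predictor is a known function of planted features.

Blobs are superellipsoids with random axis ratios and rigid rotations so
that shape descriptors (elongation, major axis, sphericity) vary in a
controlled way.  Outcomes follow an exponential proportional-hazards model
with independent exponential censoring: local-control (LC) failure times are
driven by planted PT features, a separate regional failure process by
planted LN features, and loco-regional control (LRC) fails at the earlier of
the two, so every LC failure is also an LRC failure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import VolumeWithMasks

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PlacementError",
    "generate_cohort",
    "simulate_outcomes",
    "simulate_feature_matrix",
    "write_cohort",
]

# N-stage frequencies of an advanced, node-positive head-and-neck cohort
# (all patients N+; N2b/N2c dominate).
_N_STAGE_LEVELS = ("N1", "N2a", "N2b", "N2c", "N3")
_N_STAGE_PROBS = (0.08, 0.02, 0.52, 0.33, 0.05)


class PlacementError(RuntimeError):
    """Raised when the grid is too small to place the requested blobs."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a phantom cohort.

    All lengths are millimetres.  ``ln_spread`` scales the typical distance
    from the PT centre of mass to each LN centre; ``artifact_fraction`` is
    the fraction of patients given streak-corrupted axial slices.
    """

    n_patients: int = 16
    grid_shape: tuple[int, int, int] = (48, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 1.5, 1.5)
    pt_radius_range: tuple[float, float] = (8.0, 14.0)
    n_ln_range: tuple[int, int] = (1, 4)
    ln_radius_range: tuple[float, float] = (4.0, 8.0)
    ln_spread: float = 25.0
    texture_mode: str = "smooth-noise"
    hu_mean: float = 60.0
    hu_sd: float = 20.0
    artifact_fraction: float = 0.0
    blob_shape: str = "superellipsoid"   # or "ball" for exact spheres
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for lo, hi in (self.pt_radius_range, self.ln_radius_range, self.n_ln_range):
            if lo > hi:
                raise ValueError("ranges must be non-degenerate or a point")
        if not (1 <= self.n_ln_range[0] and self.n_ln_range[1] <= 5):
            raise ValueError("n_ln_range must lie within [1, 5]")
        if self.texture_mode not in ("uniform", "smooth-noise", "two-class"):
            raise ValueError(f"unknown texture_mode {self.texture_mode!r}")
        if self.blob_shape not in ("superellipsoid", "ball"):
            raise ValueError(f"unknown blob_shape {self.blob_shape!r}")
        if not (0.0 <= self.artifact_fraction <= 1.0):
            raise ValueError("artifact_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Planted prognostic structure of a simulated cohort.

    ``planted_lc`` drives the LC failure hazard (PT features), and
    ``planted_regional`` drives a separate regional failure hazard (LN
    features).  LRC failure is the earlier of the two processes, so the
    composite endpoint always dominates the local one.  Rates are per
    month.  Defaults emulate an advanced head-and-neck cohort under
    definitive radiochemotherapy: roughly a quarter of patients fail
    locally, a third loco-regionally, with median follow-up near four
    years.
    """

    planted_lc: tuple[tuple[str, float], ...] = ()
    planted_regional: tuple[tuple[str, float], ...] = ()
    baseline_lc_rate: float = 0.004
    baseline_regional_rate: float = 0.0035
    censor_rate: float = 0.013

    def __post_init__(self):
        for name, beta in (*self.planted_lc, *self.planted_regional):
            if not np.isfinite(beta):
                raise ValueError(f"coefficient for {name!r} must be finite")
        if self.baseline_lc_rate <= 0 or self.baseline_regional_rate <= 0:
            raise ValueError("baseline rates must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation via QR of a Gaussian matrix."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _superellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: np.ndarray,
    semi_axes_mm: np.ndarray,
    exponent: float,
    rotation: np.ndarray,
) -> np.ndarray:
    """Voxelize |u/a|^p + |v/b|^p + |w/c|^p <= 1 in a rotated frame."""
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    pts = np.stack([g - c for g, c in zip(grids, center_mm)], axis=-1)
    local = pts @ rotation  # rotate into the blob's principal frame
    t = np.abs(local / semi_axes_mm) ** exponent
    return t.sum(axis=-1) <= 1.0


def _fill_texture(
    image: np.ndarray, mask: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> None:
    if spec.texture_mode == "uniform":
        image[mask] = spec.hu_mean
        return
    noise = rng.standard_normal(image.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=1.5)
    sd = smooth[mask].std()
    if sd <= 0:
        image[mask] = spec.hu_mean
        return
    smooth = (smooth - smooth[mask].mean()) / sd
    if spec.texture_mode == "smooth-noise":
        image[mask] = spec.hu_mean + spec.hu_sd * smooth[mask]
    else:  # two-class: blobby bright / dark compartments
        image[mask] = np.where(
            smooth[mask] > 0, spec.hu_mean + spec.hu_sd, spec.hu_mean - spec.hu_sd
        )


def _sample_radius(rng, lo, hi):
    return float(lo if lo == hi else rng.uniform(lo, hi))


def _place_patient(spec: PhantomSpec, rng: np.random.Generator, pid: str) -> VolumeWithMasks:
    shape = tuple(spec.grid_shape)
    spacing = spec.spacing
    extent = np.array([n * s for n, s in zip(shape, spacing)])

    # soft-tissue background with mild noise
    image = 30.0 + 8.0 * rng.standard_normal(shape)

    def _blob(c, r):
        if spec.blob_shape == "ball":
            return _superellipsoid_mask(
                shape, spacing, c, np.full(3, r), 2.0, np.eye(3)
            )
        axes = r * rng.uniform(0.7, 1.0, size=3)
        axes *= r / axes.max()
        return _superellipsoid_mask(
            shape, spacing, c, axes, rng.uniform(1.8, 3.0), _random_rotation(rng)
        )

    pt_r = _sample_radius(rng, *spec.pt_radius_range)
    center = extent / 2 + rng.uniform(-2, 2, size=3)
    pt_mask = _blob(center, pt_r)
    if not pt_mask.any():
        raise PlacementError(f"{pid}: grid too small for PT of radius {pt_r:.1f} mm")

    n_ln = int(rng.integers(spec.n_ln_range[0], spec.n_ln_range[1] + 1))
    ln_mask = np.zeros(shape, dtype=bool)
    occupied = ndimage.binary_dilation(pt_mask, iterations=1)
    margin = 2.0 * max(spacing)
    placed = 0
    for _ in range(200):
        if placed == n_ln:
            break
        ln_r = _sample_radius(rng, *spec.ln_radius_range)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        dist = max(spec.ln_spread * rng.uniform(0.6, 1.4), pt_r + ln_r + margin)
        c = center + direction * dist
        if np.any(c < ln_r) or np.any(c > extent - ln_r):
            continue
        cand = _blob(c, ln_r)
        if not cand.any() or (cand & occupied).any():
            continue
        ln_mask |= cand
        occupied |= ndimage.binary_dilation(cand, iterations=1)
        placed += 1
    if placed < n_ln:
        raise PlacementError(
            f"{pid}: could not place {n_ln} lymph nodes on a "
            f"{shape} grid (placed {placed}); enlarge the grid or shrink ln_spread"
        )

    _fill_texture(image, pt_mask | ln_mask, spec, rng)

    artifact_slices: frozenset[int] = frozenset()
    if rng.random() < spec.artifact_fraction:
        roi_slices = np.flatnonzero((pt_mask | ln_mask).any(axis=(1, 2)))
        n_bad = min(len(roi_slices), int(rng.integers(1, 4)))
        bad = rng.choice(roi_slices, size=n_bad, replace=False)
        streak = np.where(np.arange(shape[2]) % 2 == 0, 1500.0, -900.0)
        for z in bad:
            image[z] = streak[None, :]
        artifact_slices = frozenset(int(z) for z in bad)

    return VolumeWithMasks(
        patient_id=pid,
        image=image,
        spacing=spacing,
        pt_mask=pt_mask,
        ln_mask=ln_mask,
        artifact_slices=artifact_slices,
    )


def generate_cohort(spec: PhantomSpec) -> list[VolumeWithMasks]:
    """Generate a deterministic phantom cohort from a spec.

    Each patient has a connected PT mask and 1..5 LN components disjoint
    from the PT (and from each other, with at least one voxel of clearance
    so component labelling is unambiguous).  Identical specs give
    bit-identical cohorts.
    """
    cohort = []
    for i in range(spec.n_patients):
        rng = np.random.default_rng([spec.seed, i])
        cohort.append(_place_patient(spec, rng, pid=f"P{i:03d}"))
    return cohort


def _linear_predictor(
    features: pd.DataFrame, planted: Sequence[tuple[str, float]]
) -> np.ndarray:
    lp = np.zeros(len(features))
    for name, beta in planted:
        if name not in features.columns:
            raise KeyError(f"planted feature {name!r} not present in feature matrix")
        col = features[name].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        lp += beta * z
    return lp


def simulate_outcomes(
    features: pd.DataFrame, truth: GroundTruth, seed: int
) -> pd.DataFrame:
    """Draw LC and LRC outcomes from planted proportional-hazards truth.

    Features named in the ground truth are z-scored across the cohort
    before entering the linear predictor, so coefficients are per standard
    deviation.  Returns a table indexed like ``features`` with columns
    ``lc_time``, ``lc_event``, ``lrc_time``, ``lrc_event``, ``n_stage``
    (times in months).
    """
    rng = np.random.default_rng(seed)
    n = len(features)
    lp_lc = _linear_predictor(features, truth.planted_lc)
    lp_reg = _linear_predictor(features, truth.planted_regional)

    t_lc = rng.exponential(1.0 / (truth.baseline_lc_rate * np.exp(lp_lc)))
    t_reg = rng.exponential(1.0 / (truth.baseline_regional_rate * np.exp(lp_reg)))
    t_lrc = np.minimum(t_lc, t_reg)
    if truth.censor_rate > 0:
        c = rng.exponential(1.0 / truth.censor_rate, size=n)
    else:
        c = np.full(n, np.inf)

    lc_event = t_lc <= c
    lrc_event = t_lrc <= c
    out = pd.DataFrame(
        {
            "lc_time": np.minimum(t_lc, c),
            "lc_event": lc_event.astype(int),
            "lrc_time": np.minimum(t_lrc, c),
            "lrc_event": lrc_event.astype(int),
            "n_stage": rng.choice(_N_STAGE_LEVELS, size=n, p=_N_STAGE_PROBS),
        },
        index=features.index,
    )
    return out


def simulate_feature_matrix(
    n_patients: int,
    n_noise: int,
    planted_names: Sequence[str] = (),
    n_latent: int = 4,
    unique_sd: float = 0.4,
    seed: int = 0,
    prefix: str = "f",
) -> pd.DataFrame:
    """Draw a radiomics-like feature matrix with latent-factor correlation.

    Radiomic panels are strongly inter-correlated (many features are
    monotone transforms of size or heterogeneity), so the noise block is
    generated from ``n_latent`` shared Gaussian factors plus independent
    noise of standard deviation ``unique_sd``; its effective dimension is
    therefore close to ``n_latent`` rather than ``n_noise``.  Planted
    columns are independent standard normals so their prognostic signal is
    not aliased by the noise block.
    """
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_patients, n_latent))
    loadings = rng.standard_normal((n_latent, n_noise))
    noise = factors @ loadings + unique_sd * rng.standard_normal((n_patients, n_noise))
    cols = {f"{prefix}{i:03d}": noise[:, i] for i in range(n_noise)}
    for name in planted_names:
        cols[name] = rng.standard_normal(n_patients)
    df = pd.DataFrame(cols, index=[f"P{i:03d}" for i in range(n_patients)])
    return df


def write_cohort(
    cohort: Sequence[VolumeWithMasks],
    outcomes: pd.DataFrame,
    truth: GroundTruth,
    out_dir: str | Path,
    train_fraction: float = 0.6,
) -> Path:
    """Write a cohort as NIfTI volumes + masks with a clinical CSV sidecar."""
    import nibabel as nib

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for v in cohort:
        affine = np.diag([*v.spacing[::-1], 1.0])
        # store arrays as (x, y, z) on disk, matching the NIfTI convention
        nib.save(
            nib.Nifti1Image(v.image.T.astype(np.float32), affine),
            out / "images" / f"{v.patient_id}.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(v.pt_mask.T.astype(np.uint8), affine),
            out / "masks" / f"{v.patient_id}_pt.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(v.ln_mask.T.astype(np.uint8), affine),
            out / "masks" / f"{v.patient_id}_ln.nii.gz",
        )
    clin = outcomes.copy()
    clin.index.name = "patient_id"
    n_train = int(round(train_fraction * len(clin)))
    clin["cohort"] = ["training"] * n_train + ["validation"] * (len(clin) - n_train)
    clin["artifact_slices"] = [
        ";".join(map(str, sorted(v.artifact_slices))) for v in cohort
    ]
    clin.to_csv(out / "clinical.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "planted_lc": list(map(list, truth.planted_lc)),
                "planted_regional": list(map(list, truth.planted_regional)),
                "baseline_lc_rate": truth.baseline_lc_rate,
                "baseline_regional_rate": truth.baseline_regional_rate,
                "censor_rate": truth.censor_rate,
            },
            fh,
            indent=2,
        )
    return out
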