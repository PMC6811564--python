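"""The 14 lymph-node-distribution (LNPT) features.

These quantify where the involved lymph nodes sit relative to the primary
tumour, complementing the per-ROI radiomics:

1. distances between PT and LN centres of mass — mean, SD, median, min,
   max (5 features);
2. the same distances weighted by LN volume — weighted mean and SD (2);
3. volume-weighted distances additionally normalised by the PT volume (2);
4. smallest inter-structure surface distances summarised on the minimum
   spanning tree (Kruskal) over PT + LN components — mean and max edge (2);
5. the number of spatial clusters of LN voxels chosen by the
   Calinski-Harabasz index (1);
6. elongation and flatness of the joint PT u LN point cloud from a
   principal-component analysis (2).

Conventions: all statistics use the population SD (single-element sets give
0); the volume normalisation in item 3 scales the weighted statistics by
sum(v_i)/V_PT, so the mean is sum(d_i v_i)/V_PT; the MST vertex set
includes the PT; surface distances are between centres of boundary voxels.
All features are invariant to rigid motions of the structure set, and the
distance features scale linearly with the coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .datatypes import VolumeWithMasks

log = logging.getLogger(__name__)

LNPT_NAMES = (
    "lnpt_com_dist_mean",
    "lnpt_com_dist_sd",
    "lnpt_com_dist_median",
    "lnpt_com_dist_min",
    "lnpt_com_dist_max",
    "lnpt_wdist_mean",
    "lnpt_wdist_sd",
    "lnpt_nwdist_mean",
    "lnpt_nwdist_sd",
    "lnpt_mst_mean",
    "lnpt_mst_max",
    "lnpt_n_clusters",
    "lnpt_elongation",
    "lnpt_flatness",
)


@dataclass
class StructureSet:
    """Physical-space point clouds of the PT and each LN component."""

    pt_coords: np.ndarray                 # (n, 3) mm
    ln_components: list[np.ndarray]       # list of (n_i, 3) mm
    pt_volume: float                      # mm^3
    ln_volumes: list[float]               # mm^3 per component
    spacing: tuple[float, float, float]

    def __post_init__(self):
        if len(self.pt_coords) == 0:
            raise ValueError("PT must be non-empty")
        if len(self.ln_components) == 0:
            raise ValueError("at least one LN component is required")
        if any(v <= 0 for v in (self.pt_volume, *self.ln_volumes)):
            raise ValueError("structure volumes must be positive")


def structure_set_from_volume(v: VolumeWithMasks) -> StructureSet:
    """Build a StructureSet from a preprocessed patient (labelled LN)."""
    if v.ln_labels is None:
        from .preprocess import merge_ln

        v = merge_ln(v)
    spacing = np.asarray(v.spacing)
    vox = float(np.prod(spacing))
    pt = np.argwhere(v.pt_mask) * spacing
    comps, vols = [], []
    for lab in range(1, int(v.ln_labels.max()) + 1):
        c = np.argwhere(v.ln_labels == lab) * spacing
        if len(c):
            comps.append(c)
            vols.append(len(c) * vox)
    return StructureSet(pt, comps, len(pt) * vox, vols, v.spacing)


def _pop_sd(x: np.ndarray, w: np.ndarray | None = None) -> float:
    x = np.asarray(x, dtype=float)
    if w is None:
        return float(x.std())
    w = np.asarray(w, dtype=float)
    m = float((w * x).sum() / w.sum())
    return float(np.sqrt((w * (x - m) ** 2).sum() / w.sum()))


def _com_distances(s: StructureSet) -> np.ndarray:
    pt_com = s.pt_coords.mean(axis=0)
    return np.array(
        [np.linalg.norm(c.mean(axis=0) - pt_com) for c in s.ln_components]
    )


def com_distance_stats(s: StructureSet) -> dict[str, float]:
    """Item 1: statistics of PT-to-LN centre-of-mass distances."""
    d = _com_distances(s)
    return {
        "lnpt_com_dist_mean": float(d.mean()),
        "lnpt_com_dist_sd": _pop_sd(d),
        "lnpt_com_dist_median": float(np.median(d)),
        "lnpt_com_dist_min": float(d.min()),
        "lnpt_com_dist_max": float(d.max()),
    }


def weighted_distance_stats(s: StructureSet) -> dict[str, float]:
    """Item 2: the same distances weighted by LN component volume."""
    d = _com_distances(s)
    w = np.asarray(s.ln_volumes, dtype=float)
    return {
        "lnpt_wdist_mean": float((w * d).sum() / w.sum()),
        "lnpt_wdist_sd": _pop_sd(d, w),
    }


def normalized_weighted_distance_stats(s: StructureSet) -> dict[str, float]:
    """Item 3: volume-weighted distances normalised by the PT volume.

    The weighted statistics are scaled by sum(v_i)/V_PT, so the mean
    equals sum(d_i * v_i) / V_PT; larger tumours down-weight the nodal
    spread.  With sum(v_i) = V_PT this reduces to item 2.
    """
    d = _com_distances(s)
    w = np.asarray(s.ln_volumes, dtype=float)
    scale = w.sum() / s.pt_volume
    return {
        "lnpt_nwdist_mean": float((w * d).sum() / w.sum() * scale),
        "lnpt_nwdist_sd": _pop_sd(d, w) * scale,
    }


def _surface_coords(coords: np.ndarray) -> np.ndarray:
    # coordinates are few thousand at most after resampling; the KD-tree
    # query below is cheap enough on the full clouds
    return coords


def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return float(np.min(d))


def _kruskal(n: int, edges: list[tuple[float, int, int]]) -> list[float]:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    picked = []
    for w, a, b in sorted(edges):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            picked.append(w)
    return picked


def mst_distance_features(s: StructureSet) -> dict[str, float]:
    """Item 4: mean and max edge of the MST over PT + LN components.

    Edge weights are the smallest voxel-centre distances between the two
    structures; the tree is built with Kruskal's algorithm on the complete
    inter-structure graph.
    """
    clouds = [_surface_coords(s.pt_coords)] + [
        _surface_coords(c) for c in s.ln_components
    ]
    n = len(clouds)
    if n < 2:
        raise ValueError("MST features need at least two structures")
    edges = [
        (_min_distance(clouds[i], clouds[j]), i, j)
        for i in range(n)
        for j in range(i + 1, n)
    ]
    w = np.asarray(_kruskal(n, edges))
    return {"lnpt_mst_mean": float(w.mean()), "lnpt_mst_max": float(w.max())}


def cluster_count(s: StructureSet, k_max: int = 6) -> int:
    """Item 5: Calinski-Harabasz-selected number of LN voxel clusters.

    k-means (10 restarts, fixed internal seed) is run for k = 2..k_max and
    the k with the highest CH index is kept.  The index is undefined at
    k = 1, so a unimodality guard demotes the answer to 1 when the best
    2-means split has centroids closer than twice the mean within-cluster
    RMS radius; tiny or fully coincident point sets also report 1.
    """
    pts = np.vstack(s.ln_components)
    if len(pts) < 4 or np.allclose(pts.var(axis=0), 0):
        return 1
    best_k, best_ch = 1, -np.inf
    two_means_labels = None
    for k in range(2, min(k_max, len(pts) - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(pts)
        if len(np.unique(km.labels_)) < 2:
            continue
        ch = calinski_harabasz_score(pts, km.labels_)
        if k == 2:
            two_means_labels = (km.labels_, km.cluster_centers_)
        if ch > best_ch:
            best_k, best_ch = k, ch
    if best_k == 1 or two_means_labels is None:
        return 1
    labels2, centers2 = two_means_labels
    sep = np.linalg.norm(centers2[0] - centers2[1])
    radii = [
        np.sqrt(((pts[labels2 == i] - centers2[i]) ** 2).sum(axis=1).mean())
        for i in (0, 1)
        if (labels2 == i).any()
    ]
    if sep < 2.0 * np.mean(radii):
        return 1
    return best_k


def pca_elongation_flatness(s: StructureSet) -> dict[str, float]:
    """Item 6: anisotropy of the joint PT u LN point cloud."""
    pts = np.vstack([s.pt_coords, *s.ln_components])
    cov = np.cov(pts.T)
    eig = np.sort(np.clip(np.linalg.eigvalsh(cov), 0, None))[::-1]
    if eig[0] <= 0:
        log.debug("degenerate point cloud: elongation/flatness set to 0")
        return {"lnpt_elongation": 0.0, "lnpt_flatness": 0.0}
    return {
        "lnpt_elongation": float(np.sqrt(eig[1] / eig[0])),
        "lnpt_flatness": float(np.sqrt(eig[2] / eig[0])),
    }


def extract_lnpt(s: StructureSet, k_max: int = 6) -> dict[str, float]:
    """All 14 LNPT features (5 + 2 + 2 + 2 + 1 + 2)."""
    out: dict[str, float] = {}
    out.update(com_distance_stats(s))
    out.update(weighted_distance_stats(s))
    out.update(normalized_weighted_distance_stats(s))
    out.update(mst_distance_features(s))
    out["lnpt_n_clusters"] = float(cluster_count(s, k_max=k_max))
    out.update(pca_elongation_flatness(s))
    return {name: out[name] for name in LNPT_NAMES}
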