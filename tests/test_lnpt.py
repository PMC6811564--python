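"""Lymph-node distribution features: hand computations, brute-force MST,
cluster-count oracle, and rigid-motion invariance."""

import numpy as np
import pytest
from sklearn.metrics import calinski_harabasz_score

from conftest import brute_mst_weight_sets, make_ball
from noderad.lnpt import (
    LNPT_NAMES,
    StructureSet,
    cluster_count,
    com_distance_stats,
    extract_lnpt,
    mst_distance_features,
    normalized_weighted_distance_stats,
    pca_elongation_flatness,
    weighted_distance_stats,
)


def _cloud(center, n=30, radius=2.0, seed=0):
    rng = np.random.default_rng(seed)
    return np.asarray(center) + rng.uniform(-radius, radius, size=(n, 3))


def _sset(pt_center=(0, 0, 0), ln_centers=((30, 0, 0),), volumes=None, seed=0):
    pt = _cloud(pt_center, seed=seed)
    lns = [_cloud(c, seed=seed + i + 1) for i, c in enumerate(ln_centers)]
    vols = list(volumes) if volumes else [10.0] * len(lns)
    return StructureSet(pt, lns, 20.0, vols, (1.0, 1.0, 1.0))


def _point_structures(pt_pts, ln_pts_list, pt_vol=1.0, ln_vols=None):
    return StructureSet(
        np.asarray(pt_pts, float), [np.asarray(p, float) for p in ln_pts_list],
        pt_vol, ln_vols or [1.0] * len(ln_pts_list), (1.0, 1.0, 1.0),
    )


def test_single_ln_345_triangle():
    s = _point_structures([[0, 0, 0]], [[[3, 4, 0]]])
    f = com_distance_stats(s)
    assert f["lnpt_com_dist_mean"] == pytest.approx(5.0)
    assert f["lnpt_com_dist_median"] == 5.0
    assert f["lnpt_com_dist_min"] == 5.0
    assert f["lnpt_com_dist_max"] == 5.0
    assert f["lnpt_com_dist_sd"] == 0.0


def test_two_ln_distance_statistics():
    s = _point_structures([[0, 0, 0]], [[[10, 0, 0]], [[20, 0, 0]]])
    f = com_distance_stats(s)
    assert f["lnpt_com_dist_mean"] == 15.0
    assert f["lnpt_com_dist_min"] == 10.0
    assert f["lnpt_com_dist_max"] == 20.0
    assert f["lnpt_com_dist_sd"] == 5.0  # population convention


def test_coincident_com_gives_zero_min():
    s = _point_structures([[0, 0, 0], [2, 0, 0]], [[[1, 0, 0]]])
    assert com_distance_stats(s)["lnpt_com_dist_min"] == 0.0


def test_weighted_statistics():
    s = _point_structures([[0, 0, 0]], [[[10, 0, 0]], [[20, 0, 0]]],
                          ln_vols=[1.0, 9.0])
    f = weighted_distance_stats(s)
    assert f["lnpt_wdist_mean"] == pytest.approx(19.0)
    # equal volumes reduce to the unweighted mean
    s_eq = _point_structures([[0, 0, 0]], [[[10, 0, 0]], [[20, 0, 0]]],
                             ln_vols=[5.0, 5.0])
    assert weighted_distance_stats(s_eq)["lnpt_wdist_mean"] == pytest.approx(15.0)
    # single LN: spread is zero
    s1 = _point_structures([[0, 0, 0]], [[[10, 0, 0]]])
    assert weighted_distance_stats(s1)["lnpt_wdist_sd"] == 0.0


def test_normalized_weighting_scales_with_tumor_volume():
    s = _point_structures([[0, 0, 0]], [[[10, 0, 0]], [[20, 0, 0]]],
                          pt_vol=10.0, ln_vols=[1.0, 9.0])
    f = normalized_weighted_distance_stats(s)
    # sum(v) = V_PT -> identical to the plain weighted mean
    assert f["lnpt_nwdist_mean"] == pytest.approx(19.0)
    s2 = _point_structures([[0, 0, 0]], [[[10, 0, 0]], [[20, 0, 0]]],
                           pt_vol=20.0, ln_vols=[1.0, 9.0])
    assert normalized_weighted_distance_stats(s2)["lnpt_nwdist_mean"] == pytest.approx(9.5)
    s3 = _point_structures([[0, 0, 0]], [[[10, 0, 0]]], pt_vol=7.0, ln_vols=[7.0])
    assert normalized_weighted_distance_stats(s3)["lnpt_nwdist_mean"] == pytest.approx(10.0)


def test_mst_single_gap():
    s = _point_structures([[0, 0, 0], [1, 0, 0]], [[[5, 0, 0], [6, 0, 0]]])
    f = mst_distance_features(s)
    assert f["lnpt_mst_mean"] == pytest.approx(4.0)
    assert f["lnpt_mst_max"] == pytest.approx(4.0)


def test_mst_collinear_three_structures_vs_bruteforce():
    pt = [[0, 0, 0]]
    ln1 = [[5, 0, 0]]   # gap 5 to PT
    ln2 = [[12, 0, 0]]  # gap 7 to ln1, 12 to PT
    s = _point_structures(pt, [ln1, ln2])
    f = mst_distance_features(s)
    assert f["lnpt_mst_mean"] == pytest.approx(6.0)
    assert f["lnpt_mst_max"] == pytest.approx(7.0)
    edges = {(0, 1): 5.0, (1, 2): 7.0, (0, 2): 12.0}
    trees = brute_mst_weight_sets(3, edges)
    best = min(trees, key=sum)
    assert sorted([5.0, 7.0]) == best


def test_mst_optimality_bruteforce_five_structures():
    rng = np.random.default_rng(7)
    centers = rng.uniform(0, 60, size=(5, 3))
    clouds = [c + rng.uniform(-1, 1, size=(8, 3)) for c in centers]
    s = _point_structures(clouds[0], clouds[1:])
    f = mst_distance_features(s)
    edges = {}
    for i in range(5):
        for j in range(i + 1, 5):
            d = np.linalg.norm(clouds[i][:, None] - clouds[j][None], axis=-1).min()
            edges[(i, j)] = float(d)
    trees = brute_mst_weight_sets(5, edges)
    best = min(sum(t) for t in trees)
    assert f["lnpt_mst_mean"] * 4 == pytest.approx(best, rel=1e-9)
    assert all(sum(t) >= best - 1e-9 for t in trees)


def test_touching_structures_edge_is_one_voxel_step():
    s = _point_structures([[0, 0, 0]], [[[1, 0, 0]]])  # adjacent voxel centres
    f = mst_distance_features(s)
    assert f["lnpt_mst_max"] == pytest.approx(1.0)


@pytest.mark.parametrize("centers,expected", [
    ((( 0, 0, 0),), 1),
    (((0, 0, 0), (60, 0, 0)), 2),
    (((0, 0, 0), (60, 0, 0), (0, 60, 0)), 3),
])
def test_cluster_count_on_separated_blobs(centers, expected):
    lns = [_cloud(c, n=40, radius=2.5, seed=i) for i, c in enumerate(centers)]
    s = _point_structures(_cloud((100, 100, 100), seed=99), lns)
    assert cluster_count(s) == expected
    if expected > 1:
        # the chosen k really maximises the CH index computed directly
        pts = np.vstack(lns)
        labels = np.repeat(np.arange(len(lns)), [len(l) for l in lns])
        ch_true = calinski_harabasz_score(pts, labels)
        for k_other in (2, 3, 4):
            if k_other == expected:
                continue
            from sklearn.cluster import KMeans
            lab = KMeans(k_other, n_init=10, random_state=0).fit(pts).labels_
            assert ch_true >= calinski_harabasz_score(pts, lab) - 1e-6


def test_pca_isotropic_and_anisotropic():
    ball = np.argwhere(make_ball(6)).astype(float)
    s_iso = StructureSet(ball, [ball + 0.5], 10.0, [10.0], (1, 1, 1))
    f = pca_elongation_flatness(s_iso)
    assert f["lnpt_elongation"] > 0.9 and f["lnpt_flatness"] > 0.9
    s_aniso = StructureSet(ball, [ball + [0, 0, 50]], 10.0, [10.0], (1, 1, 1))
    f2 = pca_elongation_flatness(s_aniso)
    assert f2["lnpt_elongation"] < 0.5


def test_coplanar_cloud_has_vanishing_flatness():
    rng = np.random.default_rng(1)
    plane = np.c_[rng.uniform(0, 20, 50), rng.uniform(0, 20, 50), np.zeros(50)]
    s = _point_structures(plane[:25], [plane[25:] + [30, 0, 0]])
    assert pca_elongation_flatness(s)["lnpt_flatness"] < 1e-6


def test_extract_lnpt_count_and_single_ln_degeneracy():
    s = _point_structures([[0, 0, 0], [1, 1, 1]], [[[10, 0, 0], [11, 0, 0]]])
    f = extract_lnpt(s)
    assert tuple(f) == LNPT_NAMES and len(f) == 14
    assert f["lnpt_com_dist_sd"] == 0.0
    assert f["lnpt_wdist_sd"] == 0.0
    assert f["lnpt_n_clusters"] == 1.0


def test_rigid_motion_invariance_and_scale_equivariance():
    s = _sset(ln_centers=((30, 0, 0), (0, 35, 5)), volumes=(5.0, 12.0))
    ref = extract_lnpt(s)

    def apply(fun):
        return StructureSet(
            fun(s.pt_coords), [fun(c) for c in s.ln_components],
            s.pt_volume, s.ln_volumes, s.spacing,
        )

    shift = np.array([12.3, -4.5, 7.7])
    f_t = extract_lnpt(apply(lambda x: x + shift))
    th = 0.7
    rot = np.array([[np.cos(th), -np.sin(th), 0],
                    [np.sin(th), np.cos(th), 0],
                    [0, 0, 1.0]])
    f_r = extract_lnpt(apply(lambda x: x @ rot.T))
    for name in LNPT_NAMES:
        assert f_t[name] == pytest.approx(ref[name], abs=1e-9), name
        assert f_r[name] == pytest.approx(ref[name], abs=1e-9), name

    c = 2.5
    f_s = extract_lnpt(apply(lambda x: c * x))
    for name in LNPT_NAMES:
        if name in ("lnpt_n_clusters", "lnpt_elongation", "lnpt_flatness"):
            assert f_s[name] == pytest.approx(ref[name], abs=1e-9), name
        else:
            assert f_s[name] == pytest.approx(c * ref[name], rel=1e-9), name
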