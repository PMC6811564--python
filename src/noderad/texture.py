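"""3-D texture-matrix features: GLCM, GLRLM, GLSZM, NGTDM, NGLDM.

All families operate on a discretised integer grid (grey level 0 marks
voxels outside the valid ROI) and follow the IBSI reference definitions:

* GLCM — 13 unique direction offsets at Chebyshev distance 1, symmetric
  pairs; the per-direction normalised matrices are averaged before feature
  computation (25 features).
* GLRLM — runs of equal grey level along the same 13 directions, run
  matrices merged by summation (16 features).
* GLSZM — 26-connected zones of equal grey level (16 features).
* NGTDM — coarseness/contrast/busyness/complexity/strength from the
  Chebyshev-1 (26-voxel) neighbourhood averages (5 features).
* NGLDM — dependence counts with coarseness parameter alpha = 0, i.e. a
  neighbour is dependent iff it has exactly the same grey level
  (10 features).

Degenerate ROIs (a single grey level or a single voxel) cannot support some
of these statistics; entropy-type features then take the value 0 and
ratio-type features their analytic limit, with the substitution logged, so
constant phantoms never inject NaNs into downstream feature selection.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

_EPS = np.finfo(float).eps

# 13 unique direction offsets (the other 13 are their negatives)
OFFSETS_13 = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# discretisation

def discretize_fixed_width(
    image: np.ndarray, valid: np.ndarray, bin_width: float, anchor: float
) -> np.ndarray:
    """Fixed-bin-size discretisation anchored at ``anchor``.

    Grey level = floor((x - anchor)/w) + 1; values exactly at the top edge
    of the last bin are assigned to it.  Returns an integer grid with 0
    outside ``valid``.
    """
    levels = np.zeros(image.shape, dtype=np.int64)
    x = image[valid]
    lv = np.floor((x - anchor) / bin_width).astype(np.int64) + 1
    lv = np.clip(lv, 1, None)
    if x.size:
        top = int(np.floor((x.max() - anchor) / bin_width)) + 1
        # the maximum itself sits on a bin edge -> keep it in the bin below
        if np.isclose((x.max() - anchor) % bin_width, 0.0) and top > 1:
            top -= 1
        lv = np.clip(lv, 1, top)
    levels[valid] = lv
    return levels


def discretize_fixed_count(
    image: np.ndarray, valid: np.ndarray, n_bins: int
) -> np.ndarray:
    """Fixed-bin-count discretisation over the valid-voxel range."""
    levels = np.zeros(image.shape, dtype=np.int64)
    x = image[valid]
    if x.size == 0:
        return levels
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        levels[valid] = 1
        return levels
    lv = np.floor(n_bins * (x - lo) / (hi - lo)).astype(np.int64) + 1
    levels[valid] = np.minimum(lv, n_bins)
    return levels


def _pair_slices(off, shape):
    sl_a = tuple(slice(max(0, -d), n - max(0, d)) for d, n in zip(off, shape))
    sl_b = tuple(slice(max(0, d), n - max(0, -d)) for d, n in zip(off, shape))
    return sl_a, sl_b


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(levels: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Direction-averaged symmetric co-occurrence matrix (normalised)."""
    ng = int(levels[valid].max()) if valid.any() else 0
    if ng == 0:
        return np.zeros((0, 0))
    mats = []
    for off in OFFSETS_13:
        sl_a, sl_b = _pair_slices(off, levels.shape)
        ok = valid[sl_a] & valid[sl_b]
        if not ok.any():
            continue
        a = levels[sl_a][ok] - 1
        b = levels[sl_b][ok] - 1
        c = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
        c = c + c.T
        mats.append(c / c.sum())
    if not mats:
        log.debug("GLCM degenerate: no voxel pairs; zero matrix substituted")
        return np.zeros((ng, ng))
    return np.mean(mats, axis=0)


def glcm_features(p: np.ndarray) -> dict[str, float]:
    if p.size == 0 or p.sum() <= 0:
        p = np.ones((1, 1))
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((ii * p).sum())
    var = float(((ii - mu) ** 2 * p).sum())
    sigma = np.sqrt(var)

    diff = np.abs(ii - jj)
    p_diff = np.bincount(diff.ravel(), weights=p.ravel(), minlength=ng)
    k_diff = np.arange(len(p_diff))
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * ng + 1)
    k_sum = np.arange(len(p_sum))

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    diff_avg = float((k_diff * p_diff).sum())
    sum_avg = float((k_sum * p_sum).sum())

    hx = ent(px)
    hxy = ent(p.ravel())
    with np.errstate(divide="ignore"):
        lpxy = np.log2(np.outer(px, px) + _EPS)
    hxy1 = float(-(p * lpxy).sum())
    hxy2 = float(-(np.outer(px, px) * lpxy).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0
    if sigma > 0:
        correlation = float(((ii - mu) * (jj - mu) * p).sum() / (sigma * sigma))
    else:
        log.debug("GLCM single grey level: correlation substituted with 0")
        correlation = 0.0

    inv_var_mask = diff > 0
    return {
        "glcm_joint_max": float(p.max()),
        "glcm_joint_average": mu,
        "glcm_joint_variance": var,
        "glcm_entropy": hxy,
        "glcm_sum_average": sum_avg,
        "glcm_sum_variance": float(((k_sum - sum_avg) ** 2 * p_sum).sum()),
        "glcm_sum_entropy": ent(p_sum),
        "glcm_difference_average": diff_avg,
        "glcm_difference_variance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "glcm_difference_entropy": ent(p_diff),
        "glcm_asm": float((p**2).sum()),
        "glcm_contrast": float((diff**2 * p).sum()),
        "glcm_dissimilarity": float((diff * p).sum()),
        "glcm_inverse_difference": float((p / (1.0 + diff)).sum()),
        "glcm_inverse_difference_norm": float((p / (1.0 + diff / ng)).sum()),
        "glcm_inverse_difference_moment": float((p / (1.0 + diff**2)).sum()),
        "glcm_inverse_difference_moment_norm": float((p / (1.0 + diff**2 / ng**2)).sum()),
        "glcm_inverse_variance": float((p[inv_var_mask] / diff[inv_var_mask] ** 2).sum()),
        "glcm_correlation": correlation,
        "glcm_autocorrelation": float((ii * jj * p).sum()),
        "glcm_cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "glcm_cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "glcm_cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
    }


# ---------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(levels: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Run-length matrix R[level-1, length-1], merged over 13 directions.

    Runs are maximal sequences of identical grey level along a direction;
    invalid voxels break runs.  Lines are identified by the cross product
    of voxel index with the direction vector, which is invariant exactly
    along the line.
    """
    coords = np.argwhere(valid)
    if len(coords) == 0:
        return np.zeros((0, 0))
    g = levels[valid]
    ng = int(g.max())
    out_levels: list[np.ndarray] = []
    out_lengths: list[np.ndarray] = []
    for off in OFFSETS_13:
        d = np.asarray(off)
        t = coords @ d
        key = np.cross(coords, d)
        order = np.lexsort((t, key[:, 2], key[:, 1], key[:, 0]))
        kk, tt, gg = key[order], t[order], g[order]
        if len(gg) == 1:
            out_levels.append(gg)
            out_lengths.append(np.ones(1, dtype=np.int64))
            continue
        step = int(d @ d)
        cont = (
            np.all(kk[1:] == kk[:-1], axis=1)
            & (tt[1:] - tt[:-1] == step)
            & (gg[1:] == gg[:-1])
        )
        breaks = np.flatnonzero(~cont)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(gg) - 1]
        out_levels.append(gg[starts])
        out_lengths.append(ends - starts + 1)
    lv = np.concatenate(out_levels)
    ln = np.concatenate(out_lengths)
    r = np.zeros((ng, int(ln.max())), dtype=float)
    np.add.at(r, (lv - 1, ln - 1), 1.0)
    return r


def _rl_style_features(m: np.ndarray, n_valid: int, n_series: float, prefix: str,
                       names: dict[str, str]) -> dict[str, float]:
    """Shared feature formulas for run-length- and dependence-style matrices."""
    ns = m.sum()
    if ns <= 0:
        log.debug("%s degenerate: empty matrix; zeros substituted", prefix)
        return {k: 0.0 for k in names.values()}
    i = np.arange(1, m.shape[0] + 1, dtype=float)
    j = np.arange(1, m.shape[1] + 1, dtype=float)
    mi = m.sum(axis=1)
    mj = m.sum(axis=0)
    p = m / ns
    mu_i = (i * mi / ns).sum()
    mu_j = (j * mj / ns).sum()
    pe = p[p > 0]
    vals = {
        "sj_low": float((mj / j**2).sum() / ns),
        "sj_high": float((mj * j**2).sum() / ns),
        "si_low": float((mi / i**2).sum() / ns),
        "si_high": float((mi * i**2).sum() / ns),
        "lowlow": float((m / np.outer(i**2, j**2)).sum() / ns),
        "highlow": float((m * np.outer(i**2, 1.0 / j**2)).sum() / ns),
        "lowhigh": float((m * np.outer(1.0 / i**2, j**2)).sum() / ns),
        "highhigh": float((m * np.outer(i**2, j**2)).sum() / ns),
        "glnu": float((mi**2).sum() / ns),
        "glnu_norm": float((mi**2).sum() / ns**2),
        "jnu": float((mj**2).sum() / ns),
        "jnu_norm": float((mj**2).sum() / ns**2),
        "percentage": float(ns / (n_valid * n_series)) if n_valid else 0.0,
        "i_variance": float(((i - mu_i) ** 2 * mi / ns).sum()),
        "j_variance": float(((j - mu_j) ** 2 * mj / ns).sum()),
        "entropy": float(-(pe * np.log2(pe)).sum()),
        "energy": float((p**2).sum()),
    }
    return {full: vals[short] for short, full in names.items()}


def glrlm_features(r: np.ndarray, n_valid: int) -> dict[str, float]:
    names = {
        "sj_low": "glrlm_sre",
        "sj_high": "glrlm_lre",
        "si_low": "glrlm_lgre",
        "si_high": "glrlm_hgre",
        "lowlow": "glrlm_srlge",
        "highlow": "glrlm_srhge",
        "lowhigh": "glrlm_lrlge",
        "highhigh": "glrlm_lrhge",
        "glnu": "glrlm_glnu",
        "glnu_norm": "glrlm_glnu_norm",
        "jnu": "glrlm_rlnu",
        "jnu_norm": "glrlm_rlnu_norm",
        "percentage": "glrlm_run_percentage",
        "i_variance": "glrlm_gl_variance",
        "j_variance": "glrlm_rl_variance",
        "entropy": "glrlm_run_entropy",
    }
    return _rl_style_features(r, n_valid, float(len(OFFSETS_13)), "GLRLM", names)


# ---------------------------------------------------------------------------
# GLSZM

def glszm_matrix(levels: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Size-zone matrix S[level-1, size-1] using 26-connected zones."""
    g = levels[valid] if valid.any() else np.array([], dtype=np.int64)
    if g.size == 0:
        return np.zeros((0, 0))
    ng = int(g.max())
    pairs = []
    for lev in np.unique(g):
        lab, n = ndimage.label(valid & (levels == lev), structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        pairs.append((int(lev), sizes))
    max_size = max(int(s.max()) for _, s in pairs)
    m = np.zeros((ng, max_size), dtype=float)
    for lev, sizes in pairs:
        np.add.at(m, (np.full(len(sizes), lev - 1), sizes - 1), 1.0)
    return m


def glszm_features(s: np.ndarray, n_valid: int) -> dict[str, float]:
    names = {
        "sj_low": "glszm_sze",
        "sj_high": "glszm_lze",
        "si_low": "glszm_lgze",
        "si_high": "glszm_hgze",
        "lowlow": "glszm_szlge",
        "highlow": "glszm_szhge",
        "lowhigh": "glszm_lzlge",
        "highhigh": "glszm_lzhge",
        "glnu": "glszm_glnu",
        "glnu_norm": "glszm_glnu_norm",
        "jnu": "glszm_zsnu",
        "jnu_norm": "glszm_zsnu_norm",
        "percentage": "glszm_zone_percentage",
        "i_variance": "glszm_gl_variance",
        "j_variance": "glszm_zs_variance",
        "entropy": "glszm_zone_entropy",
    }
    return _rl_style_features(s, n_valid, 1.0, "GLSZM", names)


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_table(levels: np.ndarray, valid: np.ndarray):
    """Per-level occurrence probabilities p_i and summed differences s_i."""
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    vf = valid.astype(float)
    nsum = ndimage.correlate(levels * vf, kernel, mode="constant")
    ncnt = ndimage.correlate(vf, kernel, mode="constant")
    sel = valid & (ncnt > 0)
    if not sel.any():
        return np.zeros(0), np.zeros(0), 0
    a = nsum[sel] / ncnt[sel]
    gv = levels[sel]
    ng = int(gv.max())
    n_i = np.bincount(gv - 1, minlength=ng).astype(float)
    s_i = np.bincount(gv - 1, weights=np.abs(gv - a), minlength=ng)
    return n_i / n_i.sum(), s_i, int(sel.sum())


def ngtdm_features(p_i: np.ndarray, s_i: np.ndarray, n: int) -> dict[str, float]:
    if p_i.size == 0 or n == 0:
        log.debug("NGTDM degenerate: no neighbourhoods; zeros substituted")
        return {k: 0.0 for k in (
            "ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
            "ngtdm_complexity", "ngtdm_strength")}
    i = np.arange(1, len(p_i) + 1, dtype=float)
    nz = p_i > 0
    ngp = int(nz.sum())
    denom_c = float((p_i * s_i).sum())
    coarseness = 1.0 / denom_c if denom_c > 0 else 1e6
    if ngp > 1:
        pij = np.outer(p_i[nz], p_i[nz])
        dij = np.subtract.outer(i[nz], i[nz])
        contrast = float((pij * dij**2).sum()) / (ngp * (ngp - 1)) * s_i.sum() / n
        bus_den = float(np.abs(np.subtract.outer(i[nz] * p_i[nz], i[nz] * p_i[nz])).sum())
        busyness = denom_c / bus_den if bus_den > 0 else 0.0
        psum = np.add.outer(p_i[nz], p_i[nz])
        pss = np.add.outer(p_i[nz] * s_i[nz], p_i[nz] * s_i[nz])
        complexity = float((np.abs(dij) * pss / psum).sum()) / n
        strength = float((psum * dij**2).sum()) / s_i.sum() if s_i.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


# ---------------------------------------------------------------------------
# NGLDM

def ngldm_matrix(levels: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Dependence matrix D[level-1, k] with k = #equal-level 26-neighbours."""
    if not valid.any():
        return np.zeros((0, 0))
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_13:
        sl_a, sl_b = _pair_slices(off, levels.shape)
        eq = (levels[sl_a] == levels[sl_b]) & valid[sl_a] & valid[sl_b]
        dep[sl_a] += eq
        dep[sl_b] += eq
    g = levels[valid]
    k = dep[valid]
    ng = int(g.max())
    m = np.zeros((ng, 27), dtype=float)
    np.add.at(m, (g - 1, k), 1.0)
    return m[:, : k.max() + 1]


def ngldm_features(d: np.ndarray, n_valid: int) -> dict[str, float]:
    names = {
        "sj_low": "ngldm_lde",
        "sj_high": "ngldm_hde",
        "si_low": "ngldm_lgce",
        "si_high": "ngldm_hgce",
        "glnu": "ngldm_glnu",
        "jnu": "ngldm_dcnu",
        "i_variance": "ngldm_gl_variance",
        "j_variance": "ngldm_dc_variance",
        "entropy": "ngldm_dc_entropy",
        "energy": "ngldm_dc_energy",
    }
    return _rl_style_features(d, n_valid, 1.0, "NGLDM", names)


# ---------------------------------------------------------------------------

def extract_texture(levels: np.ndarray, valid: np.ndarray) -> dict[str, float]:
    """Compute all 72 texture features from a discretised grid."""
    n_valid = int(valid.sum())
    out: dict[str, float] = {}
    out.update(glcm_features(glcm_matrix(levels, valid)))
    out.update(glrlm_features(glrlm_matrix(levels, valid), n_valid))
    out.update(glszm_features(glszm_matrix(levels, valid), n_valid))
    out.update(ngtdm_features(*ngtdm_table(levels, valid)))
    out.update(ngldm_features(ngldm_matrix(levels, valid), n_valid))
    return out
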