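"""Shared fixtures and independent brute-force oracles.

The oracle implementations here are deliberately naive (explicit Python
loops, exhaustive enumeration) so they stay independent of the vectorised
implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from noderad.datatypes import VolumeWithMasks
from noderad.texture import OFFSETS_13


def make_ball(radius_vox: int, pad: int = 2) -> np.ndarray:
    """Digital ball: voxels whose centre lies within radius_vox of centre."""
    n = 2 * (radius_vox + pad) + 1
    c = (n - 1) / 2
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2


def make_volume(image, pt_mask, ln_mask, spacing=(1.0, 1.0, 1.0), **kw):
    return VolumeWithMasks(
        patient_id="T000", image=image, spacing=spacing,
        pt_mask=pt_mask, ln_mask=ln_mask, **kw,
    )


@pytest.fixture(scope="session")
def prepared_patient():
    """One preprocessed phantom patient (windowed, LN labelled)."""
    from noderad.preprocess import PreprocessConfig, preprocess_patient
    from noderad.synthetic import PhantomSpec, generate_cohort

    spec = PhantomSpec(n_patients=1, n_ln_range=(2, 3), seed=42)
    (v,) = generate_cohort(spec)
    return preprocess_patient(v, PreprocessConfig())


# ---------------------------------------------------------------------------
# brute-force texture oracles

def _in_bounds(idx, shape):
    return all(0 <= i < s for i, s in zip(idx, shape))


def brute_glcm(levels: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Direction-averaged symmetric GLCM by exhaustive pair enumeration."""
    ng = int(levels[valid].max())
    mats = []
    for off in OFFSETS_13:
        c = np.zeros((ng, ng))
        for idx in np.ndindex(levels.shape):
            j = tuple(idx[k] + off[k] for k in range(3))
            if valid[idx] and _in_bounds(j, levels.shape) and valid[j]:
                c[levels[idx] - 1, levels[j] - 1] += 1
        c = c + c.T
        if c.sum() > 0:
            mats.append(c / c.sum())
    return np.mean(mats, axis=0)


def brute_glrlm(levels: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Run-length matrix by walking every run in every direction."""
    ng = int(levels[valid].max())
    runs = []
    for off in OFFSETS_13:
        for idx in np.ndindex(levels.shape):
            if not valid[idx]:
                continue
            prev = tuple(idx[k] - off[k] for k in range(3))
            if (_in_bounds(prev, levels.shape) and valid[prev]
                    and levels[prev] == levels[idx]):
                continue  # not a run start
            length = 1
            cur = idx
            while True:
                nxt = tuple(cur[k] + off[k] for k in range(3))
                if (_in_bounds(nxt, levels.shape) and valid[nxt]
                        and levels[nxt] == levels[idx]):
                    length += 1
                    cur = nxt
                else:
                    break
            runs.append((int(levels[idx]), length))
    max_len = max(l for _, l in runs)
    r = np.zeros((ng, max_len))
    for g, l in runs:
        r[g - 1, l - 1] += 1
    return r


def brute_glszm(levels: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Size-zone matrix by breadth-first flood fill over 26-neighbours."""
    ng = int(levels[valid].max())
    seen = np.zeros(levels.shape, dtype=bool)
    zones = []
    neighbours = [o for o in itertools.product((-1, 0, 1), repeat=3) if any(o)]
    for idx in np.ndindex(levels.shape):
        if not valid[idx] or seen[idx]:
            continue
        g = levels[idx]
        stack, size = [idx], 0
        seen[idx] = True
        while stack:
            cur = stack.pop()
            size += 1
            for off in neighbours:
                nxt = tuple(cur[k] + off[k] for k in range(3))
                if (_in_bounds(nxt, levels.shape) and valid[nxt]
                        and not seen[nxt] and levels[nxt] == g):
                    seen[nxt] = True
                    stack.append(nxt)
        zones.append((int(g), size))
    max_size = max(s for _, s in zones)
    m = np.zeros((ng, max_size))
    for g, s in zones:
        m[g - 1, s - 1] += 1
    return m


def brute_mst_weight_sets(n: int, edges: dict[tuple[int, int], float]):
    """All spanning trees of the complete graph on n nodes, as weight lists."""
    all_edges = list(edges)
    trees = []
    for combo in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for a, b in combo:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            trees.append(sorted(edges[e] for e in combo))
    return trees


def random_levels(shape, n_levels, seed, p_valid=1.0):
    rng = np.random.default_rng(seed)
    levels = rng.integers(1, n_levels + 1, size=shape)
    valid = rng.random(shape) < p_valid
    levels = np.where(valid, levels, 0)
    return levels, valid
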