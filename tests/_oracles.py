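"""Independent brute-force oracles for the metric and expansion operations.

Deliberately naive: voxel-set arithmetic, all-pairs distances and KD-tree
queries, sharing no code path with the implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist


def brute_dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.count_nonzero(a & b)
    return 2.0 * inter / (np.count_nonzero(a) + np.count_nonzero(b))


def brute_boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels by explicit 6-neighbour inspection."""
    out = np.zeros_like(mask)
    idx = np.argwhere(mask)
    shape = mask.shape
    for i, j, k in idx:
        for di, dj, dk in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
            ni, nj, nk = i+di, j+dj, k+dk
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                out[i, j, k] = True
                break
            if not mask[ni, nj, nk]:
                out[i, j, k] = True
                break
    return out


def brute_h_ave(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """All-pairs boundary distance scan (O(n^2))."""
    spacing = np.asarray(spacing, dtype=float)
    pa = np.argwhere(brute_boundary(a)) * spacing
    pb = np.argwhere(brute_boundary(b)) * spacing
    d = cdist(pa, pb)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def brute_box_minkowski(mask: np.ndarray, low_vox, high_vox) -> np.ndarray:
    """Minkowski sum with the box of integer offsets [-low, +high] per axis:
    explicit union of the point set translated by every kernel offset."""
    shape = np.asarray(mask.shape)
    pts = np.argwhere(mask)
    res = np.zeros(mask.shape, dtype=bool)
    for kx in range(-int(low_vox[0]), int(high_vox[0]) + 1):
        for ky in range(-int(low_vox[1]), int(high_vox[1]) + 1):
            for kz in range(-int(low_vox[2]), int(high_vox[2]) + 1):
                q = pts + np.array([kx, ky, kz])
                ok = np.all((q >= 0) & (q < shape), axis=1)
                q = q[ok]
                res[q[:, 0], q[:, 1], q[:, 2]] = True
    return res


def brute_distance_expand(mask: np.ndarray, r_mm: float, spacing) -> np.ndarray:
    """Voxels whose centre lies within r of any mask-voxel centre (KD-tree)."""
    spacing = np.asarray(spacing, dtype=float)
    src = np.argwhere(mask) * spacing
    tree = cKDTree(src)
    all_idx = np.indices(mask.shape).reshape(3, -1).T * spacing
    dist, _ = tree.query(all_idx, k=1)
    return (dist <= r_mm).reshape(mask.shape)


def random_blob(shape, rng, n_seeds=3, grow=200) -> np.ndarray:
    """Connected random blob: union of a few random balls, clipped to grid."""
    mask = np.zeros(shape, dtype=bool)
    idx = np.indices(shape).transpose(1, 2, 3, 0)
    for _ in range(n_seeds):
        c = rng.uniform(0.25, 0.75, size=3) * np.asarray(shape)
        r = rng.uniform(2.0, 0.2 * min(shape))
        mask |= ((idx - c) ** 2).sum(axis=-1) <= r * r
    return mask
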