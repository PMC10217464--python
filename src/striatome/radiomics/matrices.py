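"""Texture-matrix builders for the six grey-level matrix families.

All builders take an integer level array (0 outside the ROI, 1..G inside)
plus the ROI mask, work fully in 3D, and return raw (un-normalised) count
matrices.  Directional families (co-occurrence, run length) return one
matrix per direction over the standard 13 unique 3D offsets; zone,
distance-zone, grey-tone-difference and dependence families produce a
single matrix using 26-connectivity neighbourhoods.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

#: the 13 unique 3D direction offsets (one per axis pair, no antiparallels)
DIRECTIONS_3D: list[tuple[int, int, int]] = [
    d
    for d in [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    if d != (0, 0, 0) and (d > (0, 0, 0))
]

#: all 26 neighbour offsets
NEIGHBOURS_26 = [d for d in
                 [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
                 if d != (0, 0, 0)]

_CONN26 = np.ones((3, 3, 3), dtype=int)


def _aligned_slices(shape, offset):
    """Index slices (sl_v, sl_n) so arr[sl_v] and arr[sl_n] pair v with v+offset."""
    sl_v, sl_n = [], []
    for n, d in zip(shape, offset):
        sl_v.append(slice(max(0, -d), n - max(0, d)))
        sl_n.append(slice(max(0, d), n + min(0, d)))
    return tuple(sl_v), tuple(sl_n)


def _shift(arr: np.ndarray, offset, fill=0) -> np.ndarray:
    """Array whose value at v is arr[v + offset] (``fill`` out of bounds)."""
    out = np.full_like(arr, fill)
    sl_v, sl_n = _aligned_slices(arr.shape, offset)
    out[sl_v] = arr[sl_n]
    return out


# ---------------------------------------------------------------------------
# co-occurrence
# ---------------------------------------------------------------------------

def glcm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Symmetrised grey-level co-occurrence matrix per direction."""
    mats = []
    for d in DIRECTIONS_3D:
        sl_v, sl_n = _aligned_slices(levels.shape, d)
        a, b = levels[sl_v], levels[sl_n]
        valid = mask[sl_v] & mask[sl_n]
        M = np.zeros((n_levels, n_levels))
        if valid.any():
            np.add.at(M, (a[valid] - 1, b[valid] - 1), 1.0)
        mats.append(M + M.T)
    return mats


# ---------------------------------------------------------------------------
# run length
# ---------------------------------------------------------------------------

def glrlm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Grey-level run-length matrix per direction (rows: level, cols: length)."""
    max_len = max(levels.shape)  # no run can exceed the longest axis
    mats = []
    for d in DIRECTIONS_3D:
        # same[v]: v and v+d both in ROI with equal level
        nxt_lvl = _shift(levels, d)
        nxt_in = _shift(mask.astype(np.uint8), d).astype(bool)
        same_fwd = mask & nxt_in & (levels == nxt_lvl)
        prv_lvl = _shift(levels, tuple(-x for x in d))
        prv_in = _shift(mask.astype(np.uint8), tuple(-x for x in d)).astype(bool)
        same_bwd = mask & prv_in & (levels == prv_lvl)
        # dynamic programme: runlen[v] = 1 + runlen[v+d] when same_fwd
        runlen = mask.astype(int)
        for _ in range(max(levels.shape)):
            new = mask * (1 + _shift(runlen, d) * same_fwd)
            if np.array_equal(new, runlen):
                break
            runlen = new
        starts = mask & ~same_bwd  # no identical predecessor: a run begins here
        g = levels[starts] - 1
        ln = runlen[starts] - 1
        M = np.zeros((n_levels, max_len))
        np.add.at(M, (g, ln), 1.0)
        mats.append(M)
    return mats


# ---------------------------------------------------------------------------
# size zone / distance zone
# ---------------------------------------------------------------------------

def _zones(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Yield (level, zone_size, zone_min_distance) per 26-connected zone."""
    # taxicab distance to outside the ROI; border voxels get 1
    padded = np.pad(mask, 1)
    dmap = ndimage.distance_transform_cdt(padded, metric="taxicab")[1:-1, 1:-1, 1:-1]
    for g in range(1, n_levels + 1):
        sel = (levels == g) & mask
        if not sel.any():
            continue
        lab, n = ndimage.label(sel, structure=_CONN26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        dists = ndimage.minimum(dmap, lab, index=np.arange(1, n + 1))
        for size, dist in zip(sizes, np.atleast_1d(dists)):
            yield g, int(size), int(dist)


def glszm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Grey-level size-zone matrix (rows: level, cols: zone size)."""
    zones = list(_zones(levels, mask, n_levels))
    max_size = max((s for _, s, _ in zones), default=1)
    M = np.zeros((n_levels, max_size))
    for g, size, _ in zones:
        M[g - 1, size - 1] += 1.0
    return M


def gldzm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Grey-level distance-zone matrix (cols: min taxicab distance to ROI edge)."""
    zones = list(_zones(levels, mask, n_levels))
    max_d = max((d for _, _, d in zones), default=1)
    M = np.zeros((n_levels, max_d))
    for g, _, dist in zones:
        M[g - 1, dist - 1] += 1.0
    return M


# ---------------------------------------------------------------------------
# neighbourhood grey tone difference
# ---------------------------------------------------------------------------

def ngtdm(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Neighbourhood grey-tone difference table.

    Returns ``(s, n)`` arrays of length ``n_levels``: ``n[i]`` counts ROI
    voxels of level i+1 that have at least one in-ROI neighbour, ``s[i]``
    sums their absolute deviation from the neighbourhood mean grey level.
    """
    nb_sum = np.zeros(levels.shape, float)
    nb_cnt = np.zeros(levels.shape, float)
    lvlf = levels.astype(float)
    m8 = mask.astype(np.uint8)
    for d in NEIGHBOURS_26:
        nb_sum += _shift(lvlf * m8, d)
        nb_cnt += _shift(m8, d)
    valid = mask & (nb_cnt > 0)
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    if valid.any():
        avg = nb_sum[valid] / nb_cnt[valid]
        g = levels[valid]
        dev = np.abs(g - avg)
        np.add.at(n, g - 1, 1.0)
        np.add.at(s, g - 1, dev)
    return s, n


# ---------------------------------------------------------------------------
# neighbouring grey level dependence
# ---------------------------------------------------------------------------

def ngldm(levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Neighbouring grey-level dependence matrix.

    Column j counts ROI voxels of each level with exactly j in-ROI
    neighbours whose level differs by at most ``alpha`` (dependence j from
    0 to 26).
    """
    dep = np.zeros(levels.shape, int)
    m8 = mask.astype(np.uint8)
    for d in NEIGHBOURS_26:
        nb_lvl = _shift(levels, d)
        nb_in = _shift(m8, d).astype(bool)
        dep += (mask & nb_in & (np.abs(levels - nb_lvl) <= alpha)).astype(int)
    g = levels[mask] - 1
    k = dep[mask]
    M = np.zeros((n_levels, int(k.max()) + 1 if k.size else 1))
    np.add.at(M, (g, k), 1.0)
    return M
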