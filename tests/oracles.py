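"""Independent brute-force oracles for texture matrices and statistics.

Everything here is deliberately written as plain loops over voxels, runs,
zones and neighbourhoods — slow, obvious, and entirely separate from the
vectorised implementations under test.
"""

from __future__ import annotations

from collections import deque

import numpy as np

NEIGHBOURS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in(shape, v):
    return all(0 <= c < n for c, n in zip(v, shape))


def glcm_oracle(levels, mask, G, offset):
    """Count aligned level pairs for one direction, then symmetrise."""
    M = np.zeros((G, G))
    for v in np.argwhere(mask):
        w = tuple(v + np.array(offset))
        if _in(mask.shape, w) and mask[w]:
            M[levels[tuple(v)] - 1, levels[w] - 1] += 1
    return M + M.T


def glrlm_oracle(levels, mask, G, offset, max_len):
    """Enumerate maximal constant-level runs along one direction."""
    M = np.zeros((G, max_len))
    d = np.array(offset)
    for v in np.argwhere(mask):
        prev = tuple(v - d)
        g = levels[tuple(v)]
        if _in(mask.shape, prev) and mask[prev] and levels[prev] == g:
            continue  # not a run start
        length = 0
        cur = v.copy()
        while _in(mask.shape, tuple(cur)) and mask[tuple(cur)] and levels[tuple(cur)] == g:
            length += 1
            cur = cur + d
        M[g - 1, length - 1] += 1
    return M


def zones_oracle(levels, mask, G):
    """(level, size, min taxicab border distance) per 26-connected zone, via BFS."""
    # taxicab distance of each mask voxel to the nearest outside voxel
    # (array border counts as outside), by multi-source BFS on the padded grid
    padded = np.pad(mask, 1)
    dist = np.full(padded.shape, -1, int)
    q = deque()
    for v in np.argwhere(~padded):
        dist[tuple(v)] = 0
        q.append(tuple(v))
    axis_nb = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while q:
        v = q.popleft()
        for d in axis_nb:
            w = tuple(np.array(v) + d)
            if _in(padded.shape, w) and dist[w] < 0:
                dist[w] = dist[v] + 1
                q.append(w)
    dmap = dist[1:-1, 1:-1, 1:-1]

    seen = np.zeros(mask.shape, bool)
    zones = []
    for v in np.argwhere(mask):
        v = tuple(v)
        if seen[v]:
            continue
        g = levels[v]
        comp = [v]
        seen[v] = True
        q = deque([v])
        while q:
            u = q.popleft()
            for d in NEIGHBOURS_26:
                w = tuple(np.array(u) + d)
                if _in(mask.shape, w) and mask[w] and not seen[w] and levels[w] == g:
                    seen[w] = True
                    comp.append(w)
                    q.append(w)
        zones.append((g, len(comp), min(dmap[c] for c in comp)))
    return zones


def glszm_oracle(levels, mask, G, max_size):
    M = np.zeros((G, max_size))
    for g, size, _ in zones_oracle(levels, mask, G):
        M[g - 1, size - 1] += 1
    return M


def gldzm_oracle(levels, mask, G, max_d):
    M = np.zeros((G, max_d))
    for g, _, dist in zones_oracle(levels, mask, G):
        M[g - 1, dist - 1] += 1
    return M


def ngtdm_oracle(levels, mask, G):
    s = np.zeros(G)
    n = np.zeros(G)
    for v in np.argwhere(mask):
        v = tuple(v)
        nb = [
            levels[tuple(np.array(v) + d)]
            for d in NEIGHBOURS_26
            if _in(mask.shape, tuple(np.array(v) + d)) and mask[tuple(np.array(v) + d)]
        ]
        if not nb:
            continue
        g = levels[v]
        n[g - 1] += 1
        s[g - 1] += abs(g - float(np.mean(nb)))
    return s, n


def ngldm_oracle(levels, mask, G, alpha=0):
    rows = {}
    for v in np.argwhere(mask):
        v = tuple(v)
        g = levels[v]
        k = sum(
            1
            for d in NEIGHBOURS_26
            if _in(mask.shape, tuple(np.array(v) + d))
            and mask[tuple(np.array(v) + d)]
            and abs(int(levels[tuple(np.array(v) + d)]) - int(g)) <= alpha
        )
        rows[(g - 1, k)] = rows.get((g - 1, k), 0) + 1
    max_k = max(k for _, k in rows)
    M = np.zeros((G, max_k + 1))
    for (i, k), c in rows.items():
        M[i, k] = c
    return M


def anova_f_oracle(group_a, group_b):
    """Closed-form one-way F for two groups."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    n = len(a) + len(b)
    grand = (a.sum() + b.sum()) / n
    ssb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    return (ssb / 1.0) / (ssw / (n - 2))


def paired_t_oracle(x, y):
    """Textbook paired t from mean/SD of differences."""
    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return t
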