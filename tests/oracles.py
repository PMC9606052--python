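"""Independent brute-force texture-matrix oracles.

Everything here is deliberately naive: explicit Python loops over voxels,
neighbors and flood fills.  These are used only to validate the vectorized
implementations on small grids; they share no code with the package.
"""
from __future__ import annotations

import numpy as np

OFFS_3D = [
    (d0, d1, d2)
    for d0 in (-1, 0, 1) for d1 in (-1, 0, 1) for d2 in (-1, 0, 1)
    if (d0, d1, d2) > (0, 0, 0)
]
OFFS_2D = [(1, 0, 0), (1, 1, 0), (0, 1, 0), (1, -1, 0)]


def _inside(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


def glcm_oracle(lv: np.ndarray, ng: int, offset) -> np.ndarray:
    """Symmetric co-occurrence counts for one offset by pair enumeration."""
    M = np.zeros((ng, ng), dtype=np.int64)
    for v in np.ndindex(lv.shape):
        if lv[v] == 0:
            continue
        w = tuple(v[a] + offset[a] for a in range(3))
        if _inside(lv.shape, w) and lv[w] > 0:
            M[lv[v] - 1, lv[w] - 1] += 1
            M[lv[w] - 1, lv[v] - 1] += 1
    return M


def glrlm_oracle(lv: np.ndarray, ng: int, offset, max_len: int) -> np.ndarray:
    """Run-length counts for one direction by walking every line voxel by voxel."""
    R = np.zeros((ng, max_len), dtype=np.int64)
    for v in np.ndindex(lv.shape):
        if lv[v] == 0:
            continue
        prev = tuple(v[a] - offset[a] for a in range(3))
        if _inside(lv.shape, prev) and lv[prev] == lv[v]:
            continue  # not a run start
        length = 1
        cur = v
        while True:
            nxt = tuple(cur[a] + offset[a] for a in range(3))
            if _inside(lv.shape, nxt) and lv[nxt] == lv[v]:
                length += 1
                cur = nxt
            else:
                break
        R[lv[v] - 1, length - 1] += 1
    return R


def _flood(lv: np.ndarray, start, neighborhood) -> list:
    level = lv[start]
    seen = {start}
    stack = [start]
    while stack:
        cur = stack.pop()
        for off in neighborhood:
            nxt = tuple(cur[a] + off[a] for a in range(3))
            if nxt not in seen and _inside(lv.shape, nxt) and lv[nxt] == level:
                seen.add(nxt)
                stack.append(nxt)
    return sorted(seen)


_N26 = [o for o in np.ndindex(3, 3, 3)]
_N26 = [(a - 1, b - 1, c - 1) for a, b, c in _N26 if (a, b, c) != (1, 1, 1)]
_N8 = [o for o in _N26 if o[2] == 0]


def zones_oracle(lv: np.ndarray, conn3d: bool = True):
    """(level, size, voxel list) of every constant-level zone via flood fill."""
    nb = _N26 if conn3d else _N8
    visited = set()
    zones = []
    for v in sorted(np.ndindex(lv.shape)):
        if lv[v] == 0 or v in visited:
            continue
        zone = _flood(lv, v, nb)
        visited.update(zone)
        zones.append((int(lv[v]), len(zone), zone))
    return zones


def glszm_oracle(lv: np.ndarray, ng: int, conn3d: bool = True) -> np.ndarray:
    zones = zones_oracle(lv, conn3d)
    smax = max((s for _, s, _ in zones), default=1)
    S = np.zeros((ng, smax), dtype=np.int64)
    for level, size, _ in zones:
        S[level - 1, size - 1] += 1
    return S


def cityblock_distance_oracle(mask: np.ndarray) -> np.ndarray:
    """Distance to the nearest out-of-mask voxel (outside the grid counts)."""
    d = np.zeros(mask.shape, dtype=np.int64)
    for v in np.ndindex(mask.shape):
        if not mask[v]:
            continue
        best = None
        for w in np.ndindex(mask.shape):
            if not mask[w]:
                dist = sum(abs(v[a] - w[a]) for a in range(3))
                best = dist if best is None else min(best, dist)
        for a in range(3):
            best_edge = min(v[a] + 1, mask.shape[a] - v[a])
            best = best_edge if best is None else min(best, best_edge)
        d[v] = best
    return d


def gldzm_oracle(lv: np.ndarray, ng: int, conn3d: bool = True) -> np.ndarray:
    zones = zones_oracle(lv, conn3d)
    dist = cityblock_distance_oracle(lv > 0)
    dmax = 1
    rows = []
    for level, _, voxels in zones:
        zd = min(int(dist[v]) for v in voxels)
        dmax = max(dmax, zd)
        rows.append((level, zd))
    D = np.zeros((ng, dmax), dtype=np.int64)
    for level, zd in rows:
        D[level - 1, zd - 1] += 1
    return D


def ngtdm_oracle(lv: np.ndarray, ng: int, conn3d: bool = True):
    """(s_i, n_i) arrays by explicit neighborhood averaging."""
    nb = _N26 if conn3d else _N8
    s = np.zeros(ng)
    n = np.zeros(ng)
    for v in np.ndindex(lv.shape):
        if lv[v] == 0:
            continue
        vals = [lv[tuple(v[a] + o[a] for a in range(3))]
                for o in nb
                if _inside(lv.shape, tuple(v[a] + o[a] for a in range(3)))
                and lv[tuple(v[a] + o[a] for a in range(3))] > 0]
        if not vals:
            continue
        s[lv[v] - 1] += abs(lv[v] - sum(vals) / len(vals))
        n[lv[v] - 1] += 1
    return s, n


def ngldm_oracle(lv: np.ndarray, ng: int, conn3d: bool = True) -> np.ndarray:
    """Dependence-count matrix (alpha = 0), columns j = count + 1."""
    nb = _N26 if conn3d else _N8
    D = np.zeros((ng, len(nb) + 1), dtype=np.int64)
    for v in np.ndindex(lv.shape):
        if lv[v] == 0:
            continue
        k = 0
        for o in nb:
            w = tuple(v[a] + o[a] for a in range(3))
            if _inside(lv.shape, w) and lv[w] == lv[v]:
                k += 1
        D[lv[v] - 1, k] += 1
    return D


def random_level_grid(rng: np.random.Generator, shape=(6, 6, 6), ng: int = 4,
                      mask_prob: float = 0.8) -> np.ndarray:
    lv = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    lv[rng.random(shape) > mask_prob] = 0
    if not (lv > 0).any():
        lv[0, 0, 0] = 1
    return lv
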