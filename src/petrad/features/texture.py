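"""Gray-level texture features over six matrix families.

Families and per-matrix feature counts:

* GLCM  (co-occurrence, 25) and GLRLM (run length, 16) with six aggregation
  methods: 2D per-slice/per-direction averaged, 2D slice-wise direction-merged,
  2.5D direction-kept slice-merged, 2.5D fully merged, 3D per-direction
  averaged, 3D direction-merged.
* GLSZM (size zone, 16), GLDZM (distance zone, 16), NGTDM (neighborhood gray
  tone difference, 5) and NGLDM (gray-level dependence, 17) with three
  aggregations: 2D averaged over slices, 2.5D slice-merged, 3D.

Total 25*6 + 16*6 + 16*3 + 16*3 + 5*3 + 17*3 = 408 features.

Conventions: gray levels are positive integers from fixed-bin-size
discretization; level 0 marks out-of-mask voxels.  Slices are taken along
the third array axis (axial planes).  GLCM uses Chebyshev distance 1
(4 in-plane directions, 13 unique 3D directions); zones are 8-connected in
2D and 26-connected in 3D; GLDZM distances are city-block distances to the
mask border (border voxels have distance 1); NGLDM uses dependence
coarseness alpha = 0 (neighbors with exactly equal level).

Single-level regions take their analytic degenerate values (zero entropies
and contrasts, correlation 1); no feature ever returns NaN.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .resample import DiscretizedVolume

__all__ = ["texture_features", "TexturePanelConfig", "TEXTURE_NAMES"]

_EPS = np.finfo(float).tiny

# in-plane offsets (axes 0, 1); slice axis is 2
_OFFS_2D = [(1, 0, 0), (1, 1, 0), (0, 1, 0), (1, -1, 0)]
# 13 unique 3D directions: lexicographically positive half of the 26-neighborhood
_OFFS_3D = [
    (d0, d1, d2)
    for d0 in (-1, 0, 1) for d1 in (-1, 0, 1) for d2 in (-1, 0, 1)
    if (d0, d1, d2) > (0, 0, 0)
]
assert len(_OFFS_3D) == 13

CM_AGGS = ["2d_avg", "2d_smrg", "2p5d_dmrg", "2p5d_mrg", "3d_avg", "3d_mrg"]
ZONE_AGGS = ["2d", "2p5d", "3d"]

GLCM_FEATURES = [
    "joint_maximum", "joint_average", "joint_variance", "joint_entropy",
    "difference_average", "difference_variance", "difference_entropy",
    "sum_average", "sum_variance", "sum_entropy", "angular_second_moment",
    "contrast", "dissimilarity", "inverse_difference",
    "inverse_difference_normalized", "inverse_difference_moment",
    "inverse_difference_moment_normalized", "inverse_variance", "correlation",
    "autocorrelation", "cluster_tendency", "cluster_shade",
    "cluster_prominence", "information_correlation_1",
    "information_correlation_2",
]
GLRLM_FEATURES = [
    "short_run_emphasis", "long_run_emphasis", "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis", "short_run_low_grey_level_emphasis",
    "short_run_high_grey_level_emphasis", "long_run_low_grey_level_emphasis",
    "long_run_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalized", "run_length_non_uniformity",
    "run_length_non_uniformity_normalized", "run_percentage",
    "grey_level_variance", "run_length_variance", "run_entropy",
]
_ZONE_FEATURES = [  # template shared by GLSZM (size) and GLDZM (distance)
    "small_{x}_emphasis", "large_{x}_emphasis", "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis", "small_{x}_low_grey_level_emphasis",
    "small_{x}_high_grey_level_emphasis", "large_{x}_low_grey_level_emphasis",
    "large_{x}_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalized", "zone_{x}_non_uniformity",
    "zone_{x}_non_uniformity_normalized", "zone_percentage",
    "grey_level_variance", "zone_{x}_variance", "zone_{x}_entropy",
]
GLSZM_FEATURES = [n.format(x="zone") for n in _ZONE_FEATURES]
GLDZM_FEATURES = [n.format(x="distance") for n in _ZONE_FEATURES]
NGTDM_FEATURES = ["coarseness", "contrast", "busyness", "complexity", "strength"]
NGLDM_FEATURES = [
    "low_dependence_emphasis", "high_dependence_emphasis",
    "low_grey_level_count_emphasis", "high_grey_level_count_emphasis",
    "low_dependence_low_grey_level_emphasis",
    "low_dependence_high_grey_level_emphasis",
    "high_dependence_low_grey_level_emphasis",
    "high_dependence_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalized", "dependence_count_non_uniformity",
    "dependence_count_non_uniformity_normalized", "dependence_count_percentage",
    "grey_level_variance", "dependence_count_variance",
    "dependence_count_entropy", "dependence_count_energy",
]


@dataclass
class TexturePanelConfig:
    """Which families, features and aggregations make up the texture panel."""

    glcm_features: list[str] = field(default_factory=lambda: list(GLCM_FEATURES))
    glrlm_features: list[str] = field(default_factory=lambda: list(GLRLM_FEATURES))
    glszm_features: list[str] = field(default_factory=lambda: list(GLSZM_FEATURES))
    gldzm_features: list[str] = field(default_factory=lambda: list(GLDZM_FEATURES))
    ngtdm_features: list[str] = field(default_factory=lambda: list(NGTDM_FEATURES))
    ngldm_features: list[str] = field(default_factory=lambda: list(NGLDM_FEATURES))
    cm_aggregations: list[str] = field(default_factory=lambda: list(CM_AGGS))
    zone_aggregations: list[str] = field(default_factory=lambda: list(ZONE_AGGS))
    glcm_distance: int = 1  # Chebyshev

    @property
    def n_features(self) -> int:
        cm = (len(self.glcm_features) + len(self.glrlm_features)) * len(self.cm_aggregations)
        zone = (len(self.glszm_features) + len(self.gldzm_features)
                + len(self.ngtdm_features) + len(self.ngldm_features)) * len(self.zone_aggregations)
        return cm + zone


def _default_names() -> list[str]:
    names = []
    for fam, feats in [("glcm", GLCM_FEATURES), ("glrlm", GLRLM_FEATURES)]:
        for agg in CM_AGGS:
            names += [f"{fam}_{agg}_{f}" for f in feats]
    for fam, feats in [("glszm", GLSZM_FEATURES), ("gldzm", GLDZM_FEATURES),
                       ("ngtdm", NGTDM_FEATURES), ("ngldm", NGLDM_FEATURES)]:
        for agg in ZONE_AGGS:
            names += [f"{fam}_{agg}_{f}" for f in feats]
    return names


TEXTURE_NAMES = _default_names()
assert len(TEXTURE_NAMES) == 408


# ---------------------------------------------------------------------------
# shared helpers


def _crop_to_mask(levels: np.ndarray, mask: np.ndarray):
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    lv = np.where(mask[sl], levels[sl], 0).astype(np.int32)
    return lv


def _mean_of_dicts(dicts: list[dict[str, float]], names: list[str]) -> dict[str, float]:
    if not dicts:
        return {n: 0.0 for n in names}
    return {n: float(np.mean([d[n] for d in dicts])) for n in names}


def _pair_slices(direction):
    src, dst = [], []
    for d in direction:
        if d >= 0:
            src.append(slice(0, None if d == 0 else -d))
            dst.append(slice(d, None))
        else:
            src.append(slice(-d, None))
            dst.append(slice(0, d))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# GLCM


def _glcm_feats(M: np.ndarray) -> dict[str, float]:
    """Features of one co-occurrence count matrix (symmetric, unnormalized)."""
    total = M.sum()
    P = M / total
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    px = P.sum(axis=1)
    ii = i[:, None]
    jj = i[None, :]
    mu = float((ii * P).sum())  # joint average; == marginal mean by symmetry
    var_x = float(((i - mu) ** 2 * px).sum())

    absdiff = np.abs(ii - jj)
    # p_{|i-j|} and p_{i+j}
    pd = np.zeros(ng)
    np.add.at(pd, absdiff.ravel(), P.ravel())
    k_d = np.arange(ng)
    ps = np.zeros(2 * ng + 1)
    np.add.at(ps, (ii + jj).ravel(), P.ravel())
    k_s = np.arange(2 * ng + 1)

    da = float((k_d * pd).sum())
    sa = float((k_s * ps).sum())
    nzP = P[P > 0]
    hxy = float(-(nzP * np.log2(nzP)).sum())
    pxpy = px[:, None] * px[None, :]
    pos = P > 0
    hxy1 = float(-(P[pos] * np.log2(pxpy[pos] + _EPS)).sum())
    posm = pxpy > 0
    hxy2 = float(-(pxpy[posm] * np.log2(pxpy[posm])).sum())
    nzx = px[px > 0]
    hx = float(-(nzx * np.log2(nzx)).sum())

    offdiag = absdiff > 0
    inv_var = float((P[offdiag] / absdiff[offdiag] ** 2).sum())
    autoc = float((ii * jj * P).sum())
    s_c = ii + jj - 2 * mu

    ic2_arg = 1.0 - np.exp(-2.0 * np.log(2.0) * (hxy2 - hxy))
    feats = {
        "joint_maximum": float(P.max()),
        "joint_average": mu,
        "joint_variance": float((((ii - mu) ** 2) * P).sum()),
        "joint_entropy": hxy,
        "difference_average": da,
        "difference_variance": float(((k_d - da) ** 2 * pd).sum()),
        "difference_entropy": float(-(pd[pd > 0] * np.log2(pd[pd > 0])).sum()),
        "sum_average": sa,
        "sum_variance": float(((k_s - sa) ** 2 * ps).sum()),
        "sum_entropy": float(-(ps[ps > 0] * np.log2(ps[ps > 0])).sum()),
        "angular_second_moment": float((P**2).sum()),
        "contrast": float((absdiff**2 * P).sum()),
        "dissimilarity": float((absdiff * P).sum()),
        "inverse_difference": float((P / (1.0 + absdiff)).sum()),
        "inverse_difference_normalized": float((P / (1.0 + absdiff / ng)).sum()),
        "inverse_difference_moment": float((P / (1.0 + absdiff**2)).sum()),
        "inverse_difference_moment_normalized": float((P / (1.0 + absdiff**2 / ng**2)).sum()),
        "inverse_variance": inv_var,
        "correlation": float((autoc - mu**2) / var_x) if var_x > 0 else 1.0,
        "autocorrelation": autoc,
        "cluster_tendency": float((s_c**2 * P).sum()),
        "cluster_shade": float((s_c**3 * P).sum()),
        "cluster_prominence": float((s_c**4 * P).sum()),
        "information_correlation_1": float((hxy - hxy1) / hx) if hx > 0 else 0.0,
        "information_correlation_2": float(np.sqrt(max(ic2_arg, 0.0))),
    }
    return feats


def _glcm_matrices(lv: np.ndarray, ng: int, offsets, per_slice: bool):
    """Count matrices per offset; per slice when ``per_slice``.

    Returns array (n_offsets, n_slices_or_1, ng, ng), symmetric counts.
    """
    nsl = lv.shape[2] if per_slice else 1
    out = np.zeros((len(offsets), nsl, ng, ng), dtype=np.int64)
    kmap = np.broadcast_to(np.arange(lv.shape[2])[None, None, :], lv.shape)
    for oi, off in enumerate(offsets):
        src, dst = _pair_slices(off)
        a, b = lv[src], lv[dst]
        valid = (a > 0) & (b > 0)
        ai, bi = a[valid] - 1, b[valid] - 1
        if per_slice:
            ks = kmap[src][valid]
            np.add.at(out[oi], (ks, ai, bi), 1)
            np.add.at(out[oi], (ks, bi, ai), 1)
        else:
            np.add.at(out[oi, 0], (ai, bi), 1)
            np.add.at(out[oi, 0], (bi, ai), 1)
    return out


# ---------------------------------------------------------------------------
# GLRLM


def _skew(lv: np.ndarray, direction):
    """Shear the grid so that lines along ``direction`` become rows.

    Returns (B, axis) where runs along ``axis`` of B are the maximal runs of
    the original grid along ``direction`` (0-padded).
    """
    d = list(direction)
    a = next(ax for ax in range(3) if d[ax] != 0)
    if d[a] < 0:
        d = [-v for v in d]
    n = lv.shape
    out_shape = [n[b] + (n[a] - 1 if (d[b] != 0 and b != a) else 0) for b in range(3)]
    B = np.zeros(out_shape, dtype=lv.dtype)
    idx = np.meshgrid(*[np.arange(nn) for nn in n], indexing="ij", sparse=True)
    tgt = []
    for b in range(3):
        if b == a or d[b] == 0:
            tgt.append(idx[b])
        else:
            shift = (n[a] - 1 - idx[a]) if d[b] > 0 else idx[a]
            tgt.append(idx[b] + shift)
    B[tuple(tgt)] = lv
    return B, a


def _runs(lv: np.ndarray, direction):
    """Maximal constant-level runs along a direction.

    Returns (run_levels, run_lengths, run_slice_index); the slice index is
    valid only for in-plane directions (direction[2] == 0).
    """
    B, a = _skew(lv, direction)
    C = np.moveaxis(B, a, -1)
    L = C.shape[-1]
    flat = C.reshape(-1, L)
    valid = flat > 0
    start = valid.copy()
    start[:, 1:] &= (flat[:, 1:] != flat[:, :-1]) | ~valid[:, :-1]
    s = start.ravel()
    v = valid.ravel()
    rid = np.cumsum(s) - 1
    n_runs = int(s.sum())
    lengths = np.bincount(rid[v], minlength=n_runs)
    run_levels = flat.ravel()[s]
    if direction[2] == 0:
        K = np.broadcast_to(np.arange(lv.shape[2])[None, None, :], lv.shape)
        KB, _ = _skew(K + 1, direction)  # +1 so 0 stays "no data"
        kflat = np.moveaxis(KB, a, -1).reshape(-1, L).ravel()
        run_slices = kflat[s] - 1
    else:
        run_slices = np.zeros(n_runs, dtype=int)
    return run_levels, lengths, run_slices


def _glrlm_feats(R: np.ndarray, nv: float) -> dict[str, float]:
    """Features of one run-length count matrix (rows: level, cols: length)."""
    N = R.sum()
    ng, nl = R.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nl + 1, dtype=float)
    g = R.sum(axis=1).astype(float)
    r = R.sum(axis=0).astype(float)
    P = R / N
    pi = g / N
    pj = r / N
    mu_i = float((i * pi).sum())
    mu_j = float((j * pj).sum())
    nz = P[P > 0]
    feats = {
        "short_run_emphasis": float((r / j**2).sum() / N),
        "long_run_emphasis": float((r * j**2).sum() / N),
        "low_grey_level_run_emphasis": float((g / i**2).sum() / N),
        "high_grey_level_run_emphasis": float((g * i**2).sum() / N),
        "short_run_low_grey_level_emphasis": float((R / (i[:, None] ** 2 * j[None, :] ** 2)).sum() / N),
        "short_run_high_grey_level_emphasis": float((R * i[:, None] ** 2 / j[None, :] ** 2).sum() / N),
        "long_run_low_grey_level_emphasis": float((R * j[None, :] ** 2 / i[:, None] ** 2).sum() / N),
        "long_run_high_grey_level_emphasis": float((R * i[:, None] ** 2 * j[None, :] ** 2).sum() / N),
        "grey_level_non_uniformity": float((g**2).sum() / N),
        "grey_level_non_uniformity_normalized": float((g**2).sum() / N**2),
        "run_length_non_uniformity": float((r**2).sum() / N),
        "run_length_non_uniformity_normalized": float((r**2).sum() / N**2),
        "run_percentage": float(N / nv),
        "grey_level_variance": float(((i - mu_i) ** 2 * pi).sum()),
        "run_length_variance": float(((j - mu_j) ** 2 * pj).sum()),
        "run_entropy": float(-(nz * np.log2(nz)).sum()),
    }
    return feats


# ---------------------------------------------------------------------------
# zone families (GLSZM / GLDZM): features from (level, size-or-distance) lists


def _zone_feats(zl: np.ndarray, zj: np.ndarray, nv: float, x: str) -> dict[str, float]:
    """Zone-list features; ``zj`` is zone size (GLSZM) or zone distance (GLDZM)."""
    names = [n.format(x=x) for n in _ZONE_FEATURES]
    N = len(zl)
    if N == 0:
        return {n: 0.0 for n in names}
    zl = zl.astype(float)
    zj = zj.astype(float)
    lv, g = np.unique(zl, return_counts=True)
    jv, r = np.unique(zj, return_counts=True)
    mu_i = zl.mean()
    mu_j = zj.mean()
    # joint probabilities via per-zone contributions (each zone weight 1/N)
    pair, cnt = np.unique(np.stack([zl, zj]), axis=1, return_counts=True)
    p = cnt / N
    vals = {
        f"small_{x}_emphasis": float((1.0 / zj**2).mean()),
        f"large_{x}_emphasis": float((zj**2).mean()),
        "low_grey_level_zone_emphasis": float((1.0 / zl**2).mean()),
        "high_grey_level_zone_emphasis": float((zl**2).mean()),
        f"small_{x}_low_grey_level_emphasis": float((1.0 / (zl**2 * zj**2)).mean()),
        f"small_{x}_high_grey_level_emphasis": float((zl**2 / zj**2).mean()),
        f"large_{x}_low_grey_level_emphasis": float((zj**2 / zl**2).mean()),
        f"large_{x}_high_grey_level_emphasis": float((zl**2 * zj**2).mean()),
        "grey_level_non_uniformity": float((g.astype(float) ** 2).sum() / N),
        "grey_level_non_uniformity_normalized": float((g.astype(float) ** 2).sum() / N**2),
        f"zone_{x}_non_uniformity": float((r.astype(float) ** 2).sum() / N),
        f"zone_{x}_non_uniformity_normalized": float((r.astype(float) ** 2).sum() / N**2),
        "zone_percentage": float(N / nv),
        "grey_level_variance": float(((zl - mu_i) ** 2).mean()),
        f"zone_{x}_variance": float(((zj - mu_j) ** 2).mean()),
        f"zone_{x}_entropy": float(-(p * np.log2(p)).sum()),
    }
    return {n: vals[n] for n in names}


_STRUCT_2D = np.ones((3, 3), dtype=int)
_STRUCT_3D = np.ones((3, 3, 3), dtype=int)


def _zones(lv: np.ndarray, struct: np.ndarray):
    """(zone_level, zone_size, zone_id_map) for one 2D or 3D region."""
    zl, zs = [], []
    id_map = np.zeros(lv.shape, dtype=np.int32)
    next_id = 1
    for level in np.unique(lv[lv > 0]):
        at = lv == level
        idx = np.argwhere(at)
        lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        lab, n = ndimage.label(at[sl], structure=struct)
        sizes = np.bincount(lab.ravel())[1:]
        zl += [level] * n
        zs += list(sizes)
        id_map[sl][lab > 0] = lab[lab > 0] + (next_id - 1)
        next_id += n
    return np.asarray(zl, dtype=np.int64), np.asarray(zs, dtype=np.int64), id_map


def _zone_distances(id_map: np.ndarray, dist_map: np.ndarray, n_zones: int) -> np.ndarray:
    if n_zones == 0:
        return np.zeros(0, dtype=np.int64)
    zmin = ndimage.minimum(dist_map, labels=id_map, index=np.arange(1, n_zones + 1))
    return np.asarray(zmin, dtype=np.int64)


def _distance_map(mask: np.ndarray) -> np.ndarray:
    """City-block distance to the nearest out-of-mask voxel; border voxels -> 1.

    The volume outside the image is treated as outside the mask.
    """
    padded = np.pad(mask, 1)
    d = ndimage.distance_transform_cdt(padded, metric="taxicab")
    sl = tuple(slice(1, -1) for _ in range(mask.ndim))
    return np.asarray(d[sl], dtype=np.int64)


# ---------------------------------------------------------------------------
# NGTDM


def _ngtdm_arrays(lv: np.ndarray, struct: np.ndarray):
    """Per-level (s_i, n_i) arrays for one 2D slice or the 3D region."""
    mask = lv > 0
    kern = struct.astype(float).copy()
    kern[tuple(s // 2 for s in kern.shape)] = 0.0
    nsum = ndimage.convolve(np.where(mask, lv, 0).astype(float), kern, mode="constant")
    ncnt = ndimage.convolve(mask.astype(float), kern, mode="constant")
    valid = mask & (ncnt > 0.5)
    abar = np.zeros(lv.shape)
    abar[valid] = nsum[valid] / ncnt[valid]
    diffs = np.abs(lv - abar)[valid]
    levels = lv[valid]
    ng = int(lv.max())
    s = np.zeros(ng + 1)
    np.add.at(s, levels, diffs)
    n = np.bincount(levels, minlength=ng + 1)
    return s[1:], n[1:].astype(float)


def _ngtdm_feats(s: np.ndarray, n: np.ndarray) -> dict[str, float]:
    nv = n.sum()
    if nv == 0:
        return {k: 0.0 for k in NGTDM_FEATURES}
    p = n / nv
    i = np.arange(1, len(n) + 1, dtype=float)
    present = p > 0
    ip, pp, sp = i[present], p[present], s[present]
    ngp = int(present.sum())
    ps = float((pp * sp).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        dif2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = float((pp[:, None] * pp[None, :] * dif2).sum()) / (ngp * (ngp - 1)) * float(s.sum()) / nv
        den_busy = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = ps / den_busy if den_busy > 0 else 0.0
        absdif = np.abs(ip[:, None] - ip[None, :])
        num_c = absdif * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]) / (pp[:, None] + pp[None, :])
        complexity = float(num_c.sum()) / nv
        num_s = ((pp[:, None] + pp[None, :]) * dif2).sum()
        strength = float(num_s) / float(s.sum()) if s.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ---------------------------------------------------------------------------
# NGLDM


def _ngldm_matrix(lv: np.ndarray, ng: int, offsets) -> np.ndarray:
    """Dependence-count matrix: rows level i, columns j = k+1 dependent neighbors."""
    mask = lv > 0
    max_k = 2 * len(offsets)
    counts = np.zeros(lv.shape, dtype=np.int32)
    for off in offsets:
        src, dst = _pair_slices(off)
        eq = (lv[src] == lv[dst]) & mask[src] & mask[dst]
        counts[src] += eq
        counts[dst] += eq
    D = np.zeros((ng, max_k + 1), dtype=np.int64)
    np.add.at(D, (lv[mask] - 1, counts[mask]), 1)
    return D


def _ngldm_feats(D: np.ndarray, nv: float) -> dict[str, float]:
    N = D.sum()
    if N == 0:
        return {k: 0.0 for k in NGLDM_FEATURES}
    ng, nk = D.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nk + 1, dtype=float)  # j = dependence count + 1
    g = D.sum(axis=1).astype(float)
    r = D.sum(axis=0).astype(float)
    P = D / N
    pi, pj = g / N, r / N
    mu_i = float((i * pi).sum())
    mu_j = float((j * pj).sum())
    nz = P[P > 0]
    return {
        "low_dependence_emphasis": float((r / j**2).sum() / N),
        "high_dependence_emphasis": float((r * j**2).sum() / N),
        "low_grey_level_count_emphasis": float((g / i**2).sum() / N),
        "high_grey_level_count_emphasis": float((g * i**2).sum() / N),
        "low_dependence_low_grey_level_emphasis": float((D / (i[:, None] ** 2 * j[None, :] ** 2)).sum() / N),
        "low_dependence_high_grey_level_emphasis": float((D * i[:, None] ** 2 / j[None, :] ** 2).sum() / N),
        "high_dependence_low_grey_level_emphasis": float((D * j[None, :] ** 2 / i[:, None] ** 2).sum() / N),
        "high_dependence_high_grey_level_emphasis": float((D * i[:, None] ** 2 * j[None, :] ** 2).sum() / N),
        "grey_level_non_uniformity": float((g**2).sum() / N),
        "grey_level_non_uniformity_normalized": float((g**2).sum() / N**2),
        "dependence_count_non_uniformity": float((r**2).sum() / N),
        "dependence_count_non_uniformity_normalized": float((r**2).sum() / N**2),
        "dependence_count_percentage": float(N / nv),
        "grey_level_variance": float(((i - mu_i) ** 2 * pi).sum()),
        "dependence_count_variance": float(((j - mu_j) ** 2 * pj).sum()),
        "dependence_count_entropy": float(-(nz * np.log2(nz)).sum()),
        "dependence_count_energy": float((P**2).sum()),
    }


# ---------------------------------------------------------------------------
# per-family drivers


def _glcm_all(lv: np.ndarray, ng: int) -> dict[str, float]:
    out = {}
    m2 = _glcm_matrices(lv, ng, _OFFS_2D, per_slice=True)  # (4, nsl, ng, ng)
    m3 = _glcm_matrices(lv, ng, _OFFS_3D, per_slice=False)  # (13, 1, ng, ng)

    per_cell = [_glcm_feats(m2[o, k]) for o in range(m2.shape[0])
                for k in range(m2.shape[1]) if m2[o, k].sum() > 0]
    out.update({f"2d_avg_{k}": v for k, v in _mean_of_dicts(per_cell, GLCM_FEATURES).items()})
    smrg = [_glcm_feats(m2[:, k].sum(axis=0)) for k in range(m2.shape[1])
            if m2[:, k].sum() > 0]
    out.update({f"2d_smrg_{k}": v for k, v in _mean_of_dicts(smrg, GLCM_FEATURES).items()})
    dmrg = [_glcm_feats(m2[o].sum(axis=0)) for o in range(m2.shape[0])
            if m2[o].sum() > 0]
    out.update({f"2p5d_dmrg_{k}": v for k, v in _mean_of_dicts(dmrg, GLCM_FEATURES).items()})
    tot2 = m2.sum(axis=(0, 1))
    mrg = [_glcm_feats(tot2)] if tot2.sum() > 0 else []
    out.update({f"2p5d_mrg_{k}": v for k, v in _mean_of_dicts(mrg, GLCM_FEATURES).items()})
    d3 = [_glcm_feats(m3[o, 0]) for o in range(m3.shape[0]) if m3[o, 0].sum() > 0]
    out.update({f"3d_avg_{k}": v for k, v in _mean_of_dicts(d3, GLCM_FEATURES).items()})
    tot3 = m3.sum(axis=(0, 1))
    mrg3 = [_glcm_feats(tot3)] if tot3.sum() > 0 else []
    out.update({f"3d_mrg_{k}": v for k, v in _mean_of_dicts(mrg3, GLCM_FEATURES).items()})
    return out


def _glrlm_all(lv: np.ndarray, ng: int) -> dict[str, float]:
    nsl = lv.shape[2]
    maxlen = max(lv.shape) + 1
    nv_slice = np.array([(lv[:, :, k] > 0).sum() for k in range(nsl)], dtype=float)
    nv_tot = float(nv_slice.sum())

    # per-(direction, slice) matrices for the in-plane directions
    R2 = np.zeros((len(_OFFS_2D), nsl, ng, maxlen), dtype=np.int64)
    for oi, off in enumerate(_OFFS_2D):
        levs, lens, ks = _runs(lv, off)
        np.add.at(R2[oi], (ks, levs - 1, lens - 1), 1)
    R3 = np.zeros((len(_OFFS_3D), ng, maxlen), dtype=np.int64)
    for oi, off in enumerate(_OFFS_3D):
        levs, lens, _ = _runs(lv, off)
        np.add.at(R3[oi], (levs - 1, lens - 1), 1)

    out = {}
    per_cell = [_glrlm_feats(R2[o, k], nv_slice[k]) for o in range(len(_OFFS_2D))
                for k in range(nsl) if R2[o, k].sum() > 0]
    out.update({f"2d_avg_{k}": v for k, v in _mean_of_dicts(per_cell, GLRLM_FEATURES).items()})
    smrg = [_glrlm_feats(R2[:, k].sum(axis=0), len(_OFFS_2D) * nv_slice[k])
            for k in range(nsl) if R2[:, k].sum() > 0]
    out.update({f"2d_smrg_{k}": v for k, v in _mean_of_dicts(smrg, GLRLM_FEATURES).items()})
    dmrg = [_glrlm_feats(R2[o].sum(axis=0), nv_tot) for o in range(len(_OFFS_2D))
            if R2[o].sum() > 0]
    out.update({f"2p5d_dmrg_{k}": v for k, v in _mean_of_dicts(dmrg, GLRLM_FEATURES).items()})
    tot2 = R2.sum(axis=(0, 1))
    mrg = [_glrlm_feats(tot2, len(_OFFS_2D) * nv_tot)] if tot2.sum() > 0 else []
    out.update({f"2p5d_mrg_{k}": v for k, v in _mean_of_dicts(mrg, GLRLM_FEATURES).items()})
    d3 = [_glrlm_feats(R3[o], nv_tot) for o in range(len(_OFFS_3D)) if R3[o].sum() > 0]
    out.update({f"3d_avg_{k}": v for k, v in _mean_of_dicts(d3, GLRLM_FEATURES).items()})
    tot3 = R3.sum(axis=0)
    mrg3 = [_glrlm_feats(tot3, len(_OFFS_3D) * nv_tot)] if tot3.sum() > 0 else []
    out.update({f"3d_mrg_{k}": v for k, v in _mean_of_dicts(mrg3, GLRLM_FEATURES).items()})
    return out


def _zone_family_all(lv: np.ndarray, family: str) -> dict[str, float]:
    """GLSZM or GLDZM for all three aggregations."""
    x = "zone" if family == "glszm" else "distance"
    names = GLSZM_FEATURES if family == "glszm" else GLDZM_FEATURES
    nsl = lv.shape[2]
    out = {}

    per_slice = []
    merged_l, merged_j = [], []
    for k in range(nsl):
        sl = lv[:, :, k]
        nv = float((sl > 0).sum())
        if nv == 0:
            continue
        zl, zs, id_map = _zones(sl, _STRUCT_2D)
        if family == "gldzm":
            zj = _zone_distances(id_map, _distance_map(sl > 0), len(zl))
        else:
            zj = zs
        per_slice.append(_zone_feats(zl, zj, nv, x))
        merged_l.append(zl)
        merged_j.append(zj)
    out.update({f"2d_{k}": v for k, v in _mean_of_dicts(per_slice, names).items()})
    nv_tot = float((lv > 0).sum())
    zl_m = np.concatenate(merged_l) if merged_l else np.zeros(0, dtype=np.int64)
    zj_m = np.concatenate(merged_j) if merged_j else np.zeros(0, dtype=np.int64)
    out.update({f"2p5d_{k}": v for k, v in _zone_feats(zl_m, zj_m, nv_tot, x).items()})

    zl3, zs3, id_map3 = _zones(lv, _STRUCT_3D)
    if family == "gldzm":
        zj3 = _zone_distances(id_map3, _distance_map(lv > 0), len(zl3))
    else:
        zj3 = zs3
    out.update({f"3d_{k}": v for k, v in _zone_feats(zl3, zj3, nv_tot, x).items()})
    return out


def _ngtdm_all(lv: np.ndarray) -> dict[str, float]:
    nsl = lv.shape[2]
    out = {}
    per_slice, s_acc, n_acc = [], None, None
    for k in range(nsl):
        sl = lv[:, :, k]
        if not (sl > 0).any():
            continue
        s, n = _ngtdm_arrays(sl, _STRUCT_2D)
        per_slice.append(_ngtdm_feats(s, n))
        ng = int(lv.max())
        s_full = np.zeros(ng)
        s_full[: len(s)] = s
        n_full = np.zeros(ng)
        n_full[: len(n)] = n
        s_acc = s_full if s_acc is None else s_acc + s_full
        n_acc = n_full if n_acc is None else n_acc + n_full
    out.update({f"2d_{k}": v for k, v in _mean_of_dicts(per_slice, NGTDM_FEATURES).items()})
    if s_acc is None:
        merged = {k: 0.0 for k in NGTDM_FEATURES}
    else:
        merged = _ngtdm_feats(s_acc, n_acc)
    out.update({f"2p5d_{k}": v for k, v in merged.items()})
    s3, n3 = _ngtdm_arrays(lv, _STRUCT_3D)
    out.update({f"3d_{k}": v for k, v in _ngtdm_feats(s3, n3).items()})
    return out


def _ngldm_all(lv: np.ndarray, ng: int) -> dict[str, float]:
    nsl = lv.shape[2]
    offs2 = [(1, 0, 0), (1, 1, 0), (0, 1, 0), (1, -1, 0)]
    out = {}
    per_slice, acc = [], None
    for k in range(nsl):
        sl = lv[:, :, k][:, :, None]
        nv = float((sl > 0).sum())
        if nv == 0:
            continue
        D = _ngldm_matrix(sl, ng, offs2)
        per_slice.append(_ngldm_feats(D, nv))
        acc = D if acc is None else acc + D
    out.update({f"2d_{k}": v for k, v in _mean_of_dicts(per_slice, NGLDM_FEATURES).items()})
    nv_tot = float((lv > 0).sum())
    merged = _ngldm_feats(acc, nv_tot) if acc is not None else {k: 0.0 for k in NGLDM_FEATURES}
    out.update({f"2p5d_{k}": v for k, v in merged.items()})
    D3 = _ngldm_matrix(lv, ng, _OFFS_3D)
    out.update({f"3d_{k}": v for k, v in _ngldm_feats(D3, nv_tot).items()})
    return out


def texture_features(disc: DiscretizedVolume,
                     panel: TexturePanelConfig | None = None) -> dict[str, float]:
    """The full 408-feature texture panel for one discretized region."""
    if panel is None:
        panel = TexturePanelConfig()
    if not disc.mask.any():
        raise ValueError("empty mask")
    lv = _crop_to_mask(disc.levels, disc.mask)
    ng = int(lv.max())

    feats: dict[str, float] = {}
    for key, val in _glcm_all(lv, ng).items():
        feats[f"glcm_{key}"] = val
    for key, val in _glrlm_all(lv, ng).items():
        feats[f"glrlm_{key}"] = val
    for fam in ("glszm", "gldzm"):
        for key, val in _zone_family_all(lv, fam).items():
            feats[f"{fam}_{key}"] = val
    for key, val in _ngtdm_all(lv).items():
        feats[f"ngtdm_{key}"] = val
    for key, val in _ngldm_all(lv, ng).items():
        feats[f"ngldm_{key}"] = val

    ordered = {name: feats[name] for name in TEXTURE_NAMES}
    assert len(ordered) == panel.n_features == 408
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise AssertionError(f"non-finite texture features: {bad[:5]}")
    return ordered
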