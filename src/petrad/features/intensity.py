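"""First-order intensity features: local intensity, statistics, histogram, IVH.

Panel layout (50 features): 2 local-intensity features (1 mL sphere means),
18 statistics of the raw in-mask SUVs, 23 statistics of the discretized
gray-level histogram (including histogram gradients), and 7
intensity-volume-histogram (IVH) features.

Degenerate regions are handled without NaN: a constant region has zero
variance/skewness/excess kurtosis, entropy 0, uniformity 1, coinciding IVH
intensities, and flat histogram gradients.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .conventional import _sphere_kernel
from .resample import DiscretizedVolume, ResampledVolume

__all__ = ["intensity_features", "INTENSITY_NAMES"]

_LOCAL = ["local_intensity_peak", "global_intensity_peak"]
_STATS = [
    "mean", "variance", "skewness", "kurtosis", "median", "minimum",
    "percentile_10", "percentile_90", "maximum", "interquartile_range",
    "range", "mean_absolute_deviation", "robust_mean_absolute_deviation",
    "median_absolute_deviation", "coefficient_of_variation",
    "quartile_coefficient_of_dispersion", "energy", "root_mean_square",
]
_HIST = [
    "ih_mean", "ih_variance", "ih_skewness", "ih_kurtosis", "ih_median",
    "ih_minimum", "ih_percentile_10", "ih_percentile_90", "ih_maximum",
    "ih_mode", "ih_interquartile_range", "ih_range",
    "ih_mean_absolute_deviation", "ih_robust_mean_absolute_deviation",
    "ih_median_absolute_deviation", "ih_coefficient_of_variation",
    "ih_quartile_coefficient_of_dispersion", "ih_entropy", "ih_uniformity",
    "ih_max_gradient", "ih_max_gradient_level", "ih_min_gradient",
    "ih_min_gradient_level",
]
_IVH = [
    "ivh_volume_at_intensity_10", "ivh_volume_at_intensity_90",
    "ivh_intensity_at_volume_10", "ivh_intensity_at_volume_90",
    "ivh_volume_fraction_difference", "ivh_intensity_difference", "ivh_auc",
]
INTENSITY_NAMES = _LOCAL + _STATS + _HIST + _IVH


def _moments(x: np.ndarray) -> dict[str, float]:
    """Location/spread statistics shared by the raw-SUV and histogram blocks."""
    mu = float(x.mean())
    var = float(x.var())  # population variance
    sd = np.sqrt(var)
    skew = float(((x - mu) ** 3).mean() / sd**3) if sd > 0 else 0.0
    kurt = float(((x - mu) ** 4).mean() / sd**4 - 3.0) if sd > 0 else 0.0
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    return {
        "mean": mu,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": float(med),
        "minimum": float(x.min()),
        "percentile_10": float(p10),
        "percentile_90": float(p90),
        "maximum": float(x.max()),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.abs(x - mu).mean()),
        "robust_mean_absolute_deviation": rmad,
        "median_absolute_deviation": float(np.abs(x - med).mean()),
        "coefficient_of_variation": sd / mu if mu != 0 else 0.0,
        "quartile_coefficient_of_dispersion": float((p75 - p25) / (p75 + p25)) if (p75 + p25) != 0 else 0.0,
    }


def _local_peaks(volume: ResampledVolume) -> tuple[float, float]:
    mask = volume.mask
    kern = _sphere_kernel(volume.spacing)
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - [s // 2 for s in kern.shape], 0)
    hi = np.minimum(idx.max(axis=0) + [s // 2 + 1 for s in kern.shape], mask.shape)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    data = volume.suv[sl]
    msk = mask[sl]
    num = ndimage.convolve(data, kern, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(data), kern, mode="constant", cval=0.0)
    means = num / den
    global_peak = float(means[msk].max())
    vmax = data[msk].max()
    at_max = msk & (data == vmax)
    local_peak = float(means[at_max].max())
    return local_peak, global_peak


def intensity_features(volume: ResampledVolume, disc: DiscretizedVolume) -> dict[str, float]:
    x = volume.suv[volume.mask].astype(np.float64)
    if x.size < 1:
        raise ValueError("empty mask")

    feats: dict[str, float] = {}
    local_peak, global_peak = _local_peaks(volume)
    feats["local_intensity_peak"] = local_peak
    feats["global_intensity_peak"] = global_peak

    feats.update(_moments(x))
    feats["energy"] = float((x**2).sum())
    feats["root_mean_square"] = float(np.sqrt((x**2).mean()))

    # --- histogram block over gray levels 1..Ng --------------------------
    g = disc.levels[disc.mask].astype(np.float64)
    ng = disc.n_levels
    counts = np.bincount(g.astype(int), minlength=ng + 1)[1:]
    p = counts / counts.sum()
    hm = _moments(g)
    feats.update({f"ih_{k}": v for k, v in hm.items()})
    feats["ih_mode"] = float(np.argmax(counts) + 1)
    nz = p[p > 0]
    feats["ih_entropy"] = float(-(nz * np.log2(nz)).sum())
    feats["ih_uniformity"] = float((p**2).sum())
    if ng > 1:
        grad = np.empty(ng)
        grad[0] = counts[1] - counts[0]
        grad[-1] = counts[-1] - counts[-2]
        if ng > 2:
            grad[1:-1] = (counts[2:] - counts[:-2]) / 2.0
        feats["ih_max_gradient"] = float(grad.max())
        feats["ih_max_gradient_level"] = float(np.argmax(grad) + 1)
        feats["ih_min_gradient"] = float(grad.min())
        feats["ih_min_gradient_level"] = float(np.argmin(grad) + 1)
    else:
        feats["ih_max_gradient"] = 0.0
        feats["ih_max_gradient_level"] = 1.0
        feats["ih_min_gradient"] = 0.0
        feats["ih_min_gradient_level"] = 1.0

    # --- intensity-volume histogram --------------------------------------
    xmin, xmax = float(x.min()), float(x.max())
    n = x.size
    if xmax > xmin:
        def vfrac(theta: float) -> float:
            return float((x >= theta).sum()) / n

        theta10 = xmin + 0.10 * (xmax - xmin)
        theta90 = xmin + 0.90 * (xmax - xmin)
        v10, v90 = vfrac(theta10), vfrac(theta90)
        xs = np.sort(x)[::-1]
        i10 = float(xs[max(int(np.ceil(0.10 * n)) - 1, 0)])
        i90 = float(xs[max(int(np.ceil(0.90 * n)) - 1, 0)])
        thetas = np.linspace(xmin, xmax, 1000)
        fracs = (x[None, :] >= thetas[:, None]).mean(axis=1)
        auc = float(np.trapezoid(fracs, dx=1.0 / (len(thetas) - 1)))
    else:
        v10 = v90 = 1.0
        i10 = i90 = xmin
        auc = 1.0
    feats["ivh_volume_at_intensity_10"] = v10
    feats["ivh_volume_at_intensity_90"] = v90
    feats["ivh_intensity_at_volume_10"] = i10
    feats["ivh_intensity_at_volume_90"] = i90
    feats["ivh_volume_fraction_difference"] = v10 - v90
    feats["ivh_intensity_difference"] = i10 - i90
    feats["ivh_auc"] = auc

    ordered = {name: feats[name] for name in INTENSITY_NAMES}
    assert len(ordered) == 50
    return ordered
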