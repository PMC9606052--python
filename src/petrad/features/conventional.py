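"""Conventional PET features, computed on the original (non-resampled) grid."""
from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["suv_peak", "conventional_pet", "CONVENTIONAL_NAMES"]

CONVENTIONAL_NAMES = ["mtv_ml", "suv_max", "suv_peak", "suv_mean", "tlg"]

#: radius (mm) of the 1 mL sphere used for SUVpeak
_R_1ML = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def _sphere_kernel(spacing) -> np.ndarray:
    """Binary kernel of voxels whose centers lie within the 1 mL sphere."""
    half = [int(np.ceil(_R_1ML / s)) for s in spacing]
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return (gx**2 + gy**2 + gz**2 <= _R_1ML**2).astype(float)


def suv_peak(image, mask: np.ndarray) -> float:
    """EANM-style SUVpeak: the highest mean SUV in a ~1 mL sphere centered on
    any in-VOI voxel.  The sphere may extend outside the VOI; at image borders
    only the in-grid part of the sphere contributes.
    """
    if not mask.any():
        raise ValueError("empty VOI")
    kern = _sphere_kernel(image.spacing)
    # crop to the mask bounding box plus the kernel support for speed
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - [s // 2 for s in kern.shape], 0)
    hi = np.minimum(idx.max(axis=0) + [s // 2 + 1 for s in kern.shape], mask.shape)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    data = image.data[sl]
    msk = mask[sl]
    num = ndimage.convolve(data, kern, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(data), kern, mode="constant", cval=0.0)
    means = num / den
    return float(means[msk].max())


def conventional_pet(image, mask: np.ndarray) -> dict[str, float]:
    """MTV (mL), SUVmax, SUVpeak, SUVmean and TLG (= MTV * SUVmean) for a VOI.

    ``mask`` may be a single lesion or the union of all lesions (patient VOI).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty VOI")
    vals = image.data[mask]
    mtv = float(mask.sum()) * image.voxel_volume_ml
    mean = float(vals.mean())
    return {
        "mtv_ml": mtv,
        "suv_max": float(vals.max()),
        "suv_peak": suv_peak(image, mask),
        "suv_mean": mean,
        "tlg": mtv * mean,
    }
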