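"""Grid resampling and fixed-bin-size discretization.

Images are resampled to 2 mm isotropic voxels with centered-grid tri-linear
interpolation (the output grid shares its geometric center with the input
grid), and in-mask SUVs are discretized with a fixed 0.25-SUV bin width
anchored at 0 so gray levels are comparable across lesions and patients:

    level(x) = floor((x - anchor) / bin_width) + 1
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..image import SuvImage

__all__ = ["ResampledVolume", "DiscretizedVolume", "resample", "discretize"]


@dataclass
class ResampledVolume:
    suv: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    source_spacing: tuple[float, float, float]
    interpolation: str = "trilinear"

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def as_image(self) -> SuvImage:
        return SuvImage(self.suv, self.spacing, self.origin)


@dataclass
class DiscretizedVolume:
    levels: np.ndarray  # int grid; 0 outside mask
    mask: np.ndarray
    bin_width: float
    anchor: float
    n_levels: int
    spacing: tuple[float, float, float]


def resample(image: SuvImage, mask: np.ndarray,
             spacing=(2.0, 2.0, 2.0)) -> ResampledVolume:
    """Resample image and mask onto an isotropic grid with a shared center.

    The SUV grid is tri-linearly interpolated; the mask is interpolated
    tri-linearly as a float field and thresholded at 0.5.  When the input
    already has the target spacing the operation is the identity.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    sp_in = np.asarray(image.spacing)
    sp_out = np.asarray(spacing, dtype=float)
    n_in = np.asarray(image.shape)
    n_out = np.ceil(n_in * sp_in / sp_out).astype(int)
    center = image.grid_center_mm
    origin_out = center - (n_out - 1) / 2.0 * sp_out

    grids = np.meshgrid(*[np.arange(n) for n in n_out], indexing="ij")
    coords = [
        (origin_out[a] + grids[a] * sp_out[a] - image.origin[a]) / sp_in[a]
        for a in range(3)
    ]
    suv = ndimage.map_coordinates(image.data, coords, order=1, mode="nearest")
    mfloat = ndimage.map_coordinates(mask.astype(np.float64), coords, order=1,
                                     mode="constant", cval=0.0)
    return ResampledVolume(
        suv=suv,
        mask=mfloat >= 0.5,
        spacing=tuple(sp_out),
        origin=tuple(origin_out),
        source_spacing=tuple(sp_in),
    )


def discretize(volume: ResampledVolume, bin_width: float = 0.25,
               anchor: float = 0.0) -> DiscretizedVolume:
    """Fixed-bin-size gray-level discretization of the in-mask SUVs."""
    vals = volume.suv[volume.mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite SUV inside the mask")
    if np.any(vals <= anchor - bin_width):
        raise ValueError("in-mask SUVs must exceed anchor - bin_width")
    levels = np.zeros(volume.suv.shape, dtype=np.int32)
    lv = np.floor((vals - anchor) / bin_width).astype(np.int32) + 1
    lv = np.maximum(lv, 1)
    levels[volume.mask] = lv
    return DiscretizedVolume(
        levels=levels,
        mask=volume.mask,
        bin_width=bin_width,
        anchor=anchor,
        n_levels=int(lv.max()),
        spacing=volume.spacing,
    )
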