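"""3D SUV image container with physical geometry and NIfTI round-tripping.

The PET voxel unit throughout the package is the standardized uptake value
(SUV): tissue FDG concentration normalized by injected dose and body weight.
Images are axis-aligned scalar grids; world coordinates (mm) are
``origin + index * spacing``.
"""
from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["SuvImage"]


@dataclass
class SuvImage:
    """A 3D SUV grid with voxel spacing (mm) and origin (mm).

    ``data`` is indexed ``[i, j, k]``; voxel centers sit at
    ``origin + (i, j, k) * spacing``.  Orientation is axis-aligned (no
    rotation component), which suffices for phantom work and keeps all
    geometry exact.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to world mm coordinates (voxel centers)."""
        idx = np.atleast_2d(np.asarray(idx, dtype=np.float64))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map (n, 3) world mm coordinates to fractional voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=np.float64))
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    @property
    def grid_center_mm(self) -> np.ndarray:
        """World coordinate of the geometric center of the voxel-center grid."""
        n = np.asarray(self.shape, dtype=np.float64)
        return np.asarray(self.origin) + (n - 1.0) / 2.0 * np.asarray(self.spacing)

    def crop(self, lo, hi) -> "SuvImage":
        """Sub-image over the half-open index box [lo, hi); origin adjusted."""
        lo = np.clip(np.asarray(lo, dtype=int), 0, None)
        hi = np.minimum(np.asarray(hi, dtype=int), self.shape)
        sub = self.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        new_origin = np.asarray(self.origin) + lo * np.asarray(self.spacing)
        return SuvImage(sub.copy(), self.spacing, tuple(new_origin))

    # --- NIfTI I/O -------------------------------------------------------

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine())

    def save(self, path: str) -> None:
        nib.save(self.to_nifti(), path)

    @classmethod
    def load(cls, path: str) -> "SuvImage":
        img = nib.load(path)
        aff = img.affine
        spacing = tuple(float(abs(aff[i, i])) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        return cls(np.asarray(img.get_fdata(), dtype=np.float64), spacing, origin)


def save_label_map(labels: np.ndarray, like: SuvImage, path: str) -> None:
    """Write an integer lesion label map aligned to ``like`` as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), like.affine()), path)


def load_label_map(path: str) -> np.ndarray:
    return np.asarray(nib.load(path).get_fdata(), dtype=np.int32)
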