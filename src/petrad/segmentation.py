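"""Lesion delineation by fixed SUV threshold with volume filtering.

Mirrors the fully automated preselection used for FDG-avid lymphoma lesions:
26-connected components of voxels with SUV >= 4.0 are kept when their volume
is >= 3 mL.  Manual curation is emulated programmatically: sub-threshold-volume
lesions can be added from a seed voxel, and non-tumor regions removed by label.
A simple scan quality-control rule (hepatic SUV, plasma glucose, image
activity fraction) is provided as advisory metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import SuvImage
from .features.conventional import suv_peak as _suv_peak

__all__ = ["LesionSet", "QcRecord", "delineate", "add_lesion", "remove_region",
           "check_scan_quality"]

_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class LesionSummary:
    label: int
    n_voxels: int
    volume_ml: float
    centroid_mm: np.ndarray  # volume-weighted (uniform voxel weights)
    suv_max: float
    suv_mean: float
    suv_peak: float


@dataclass
class LesionSet:
    """Labeled lesion masks over an image with per-lesion summaries.

    Labels are contiguous positive integers ordered by decreasing volume
    (ties broken by lexicographic centroid order); 0 is background.
    """

    image: SuvImage
    label_map: np.ndarray
    lesions: list[LesionSummary] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.lesions)

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    def mask(self, label: int | None = None) -> np.ndarray:
        if label is None:
            return self.label_map > 0
        return self.label_map == label

    @property
    def mtv_ml(self) -> float:
        return float(sum(les.volume_ml for les in self.lesions))

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": les.label,
                "n_voxels": les.n_voxels,
                "volume_ml": les.volume_ml,
                "centroid_x_mm": les.centroid_mm[0],
                "centroid_y_mm": les.centroid_mm[1],
                "centroid_z_mm": les.centroid_mm[2],
                "suv_max": les.suv_max,
                "suv_mean": les.suv_mean,
                "suv_peak": les.suv_peak,
            }
            for les in self.lesions
        ]
        return pd.DataFrame(rows)


def _summarize(image: SuvImage, labels: np.ndarray, n: int) -> list[LesionSummary]:
    voxvol = image.voxel_volume_ml
    out = []
    for k in range(1, n + 1):
        mask = labels == k
        nvox = int(mask.sum())
        idx = np.argwhere(mask)
        centroid = image.index_to_world(idx).mean(axis=0)
        vals = image.data[mask]
        out.append(
            LesionSummary(
                label=k,
                n_voxels=nvox,
                volume_ml=nvox * voxvol,
                centroid_mm=centroid,
                suv_max=float(vals.max()),
                suv_mean=float(vals.mean()),
                suv_peak=_suv_peak(image, mask),
            )
        )
    return out


def _relabel_by_volume(image: SuvImage, labels: np.ndarray) -> LesionSet:
    """Renumber components by decreasing volume, centroid-lexicographic ties."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    keyed = []
    for k in ids:
        mask = labels == k
        nvox = int(mask.sum())
        centroid = tuple(np.round(image.index_to_world(np.argwhere(mask)).mean(axis=0), 9))
        keyed.append((-nvox, centroid, k))
    keyed.sort()
    new_labels = np.zeros_like(labels, dtype=np.int32)
    for new_id, (_, _, old) in enumerate(keyed, start=1):
        new_labels[labels == old] = new_id
    lset = LesionSet(image, new_labels)
    lset.lesions = _summarize(image, new_labels, len(keyed))
    return lset


def delineate(image: SuvImage, suv_threshold: float = 4.0,
              min_volume_ml: float = 3.0) -> LesionSet:
    """Automated lesion preselection.

    Keeps every 26-connected component of ``{SUV >= suv_threshold}`` with
    volume >= ``min_volume_ml``.  An empty selection is a valid, empty
    LesionSet.
    """
    if not np.all(np.isfinite(image.data)):
        raise ValueError("image contains non-finite voxels")
    mask = image.data >= suv_threshold
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return LesionSet(image, np.zeros(image.shape, dtype=np.int32))
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    min_vox = min_volume_ml / image.voxel_volume_ml
    keep = np.flatnonzero(counts >= min_vox)
    keep = keep[keep > 0]
    filtered = np.where(np.isin(labels, keep), labels, 0)
    return _relabel_by_volume(image, filtered)


def add_lesion(lesions: LesionSet, image: SuvImage, seed_voxel,
               suv_threshold: float = 4.0) -> LesionSet:
    """Add the thresholded component containing ``seed_voxel`` regardless of volume.

    Emulates the single-click addition of small (< 3 mL) lymphoma lesions
    missed by the volume filter.  Idempotent when the seed already lies in a
    selected lesion.
    """
    seed = tuple(int(v) for v in seed_voxel)
    if image.data[seed] < suv_threshold:
        raise ValueError(
            f"seed voxel {seed} has SUV {image.data[seed]:.2f} < threshold {suv_threshold}"
        )
    if lesions.label_map[seed] > 0:
        return lesions
    mask = image.data >= suv_threshold
    comp_labels, _ = ndimage.label(mask, structure=_CONN26)
    component = comp_labels == comp_labels[seed]
    merged = lesions.label_map.copy()
    merged[component] = merged.max() + 1
    return _relabel_by_volume(image, merged)


def remove_region(lesions: LesionSet, lesion_id: int) -> LesionSet:
    """Remove one lesion by label (emulating manual deletion of non-tumor uptake)."""
    if not any(les.label == lesion_id for les in lesions.lesions):
        raise KeyError(f"no lesion with label {lesion_id}; "
                       f"have {[les.label for les in lesions.lesions]}")
    pruned = lesions.label_map.copy()
    pruned[pruned == lesion_id] = 0
    return _relabel_by_volume(lesions.image, pruned)


@dataclass
class QcRecord:
    hepatic_suv_mean: float
    plasma_glucose: float
    image_activity_fraction: float | None
    verdict: str
    reason: str


def check_scan_quality(hepatic_suv_mean: float, plasma_glucose: float,
                       image_activity_fraction: float | None = None) -> QcRecord:
    """Scan-level quality control.

    ``pass`` when mean hepatic SUV lies in [1.3, 3.0] and plasma glucose is
    below 11 mmol/L; a scan with out-of-range hepatic SUV is still accepted
    (``pass_by_activity``) when 50-80% of the injected activity is in the
    image; otherwise ``fail``.
    """
    for name, v in [("hepatic_suv_mean", hepatic_suv_mean), ("plasma_glucose", plasma_glucose)]:
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {v}")
    if plasma_glucose >= 11.0:
        return QcRecord(hepatic_suv_mean, plasma_glucose, image_activity_fraction,
                        "fail", f"plasma glucose {plasma_glucose:.1f} >= 11 mmol/L")
    if 1.3 <= hepatic_suv_mean <= 3.0:
        return QcRecord(hepatic_suv_mean, plasma_glucose, image_activity_fraction,
                        "pass", "hepatic SUV and glucose within range")
    if image_activity_fraction is not None and 0.50 <= image_activity_fraction <= 0.80:
        return QcRecord(hepatic_suv_mean, plasma_glucose, image_activity_fraction,
                        "pass_by_activity",
                        f"hepatic SUV {hepatic_suv_mean:.2f} out of [1.3, 3.0] but "
                        f"activity fraction {image_activity_fraction:.2f} in [0.50, 0.80]")
    return QcRecord(hepatic_suv_mean, plasma_glucose, image_activity_fraction,
                    "fail", f"hepatic SUV {hepatic_suv_mean:.2f} out of [1.3, 3.0] and "
                            "activity fraction unavailable or out of [0.50, 0.80]")
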