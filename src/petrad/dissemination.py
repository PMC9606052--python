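"""Patient-level dissemination features.

Eighteen features quantifying how disease is spread across lesions: the
lesion count, four inter-lesion distance features (Dmax/Dmean from the bulk
lesion and over all lesion pairs), ten intensity-spread features (range, SD,
coefficient of variation, max/min ratio and interquartile range of the
per-lesion SUVpeak and SUVmean), and three volume-spread features (volume
range, volume SD and the bulk volume fraction, i.e. the largest lesion's
share of the patient MTV).

Distances are Euclidean distances between volume-weighted lesion centroids
in physical mm ("bulk" = largest-volume lesion, ties broken by label order).
Single-lesion patients take pinned degenerate values: all distance and
spread features 0, ratios 1, bulk fraction 1.
"""
from __future__ import annotations

import numpy as np

from .segmentation import LesionSet

__all__ = ["DISSEMINATION_NAMES", "centroid_distances", "dissemination_features"]

DISSEMINATION_NAMES = [
    "n_lesions",
    "dmax_bulk_mm", "dmax_patient_mm", "dmean_bulk_mm", "dmean_patient_mm",
    "suv_peak_range", "suv_peak_sd", "suv_peak_cov", "suv_peak_max_min_ratio",
    "suv_peak_iqr",
    "suv_mean_range", "suv_mean_sd", "suv_mean_cov", "suv_mean_max_min_ratio",
    "suv_mean_iqr",
    "volume_range_ml", "volume_sd_ml", "bulk_volume_fraction",
]


def centroid_distances(lesions: LesionSet) -> np.ndarray:
    """Pairwise Euclidean distances (mm) between lesion centroids."""
    if lesions.n_lesions < 1:
        raise ValueError("need at least one lesion")
    c = np.array([les.centroid_mm for les in lesions.lesions])
    return np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)


def _spread(x: np.ndarray) -> dict[str, float]:
    if len(x) == 1:
        return {"range": 0.0, "sd": 0.0, "cov": 0.0, "max_min_ratio": 1.0, "iqr": 0.0}
    p25, p75 = np.percentile(x, [25, 75])
    sd = float(x.std())  # population SD
    mean = float(x.mean())
    return {
        "range": float(x.max() - x.min()),
        "sd": sd,
        "cov": sd / mean if mean != 0 else 0.0,
        "max_min_ratio": float(x.max() / x.min()) if x.min() > 0 else 0.0,
        "iqr": float(p75 - p25),
    }


def dissemination_features(lesions: LesionSet) -> dict[str, float]:
    """The 18 dissemination features for one patient."""
    n = lesions.n_lesions
    if n < 1:
        raise ValueError("need at least one lesion")
    volumes = np.array([les.volume_ml for les in lesions.lesions])
    if np.any(volumes <= 0):
        raise ValueError("zero-volume lesion")
    peaks = np.array([les.suv_peak for les in lesions.lesions])
    means = np.array([les.suv_mean for les in lesions.lesions])
    bulk = int(np.argmax(volumes))  # labels are volume-ordered so this is 0

    if n > 1:
        dmat = centroid_distances(lesions)
        others = np.delete(dmat[bulk], bulk)
        iu = np.triu_indices(n, k=1)
        feats_dist = {
            "dmax_bulk_mm": float(others.max()),
            "dmax_patient_mm": float(dmat.max()),
            "dmean_bulk_mm": float(others.mean()),
            "dmean_patient_mm": float(dmat[iu].mean()),
        }
    else:
        feats_dist = {"dmax_bulk_mm": 0.0, "dmax_patient_mm": 0.0,
                      "dmean_bulk_mm": 0.0, "dmean_patient_mm": 0.0}

    out: dict[str, float] = {"n_lesions": float(n)}
    out.update(feats_dist)
    for prefix, x in [("suv_peak", peaks), ("suv_mean", means)]:
        for key, val in _spread(x).items():
            out[f"{prefix}_{key}"] = val
    vspread = _spread(volumes)
    out["volume_range_ml"] = vspread["range"]
    out["volume_sd_ml"] = vspread["sd"]
    out["bulk_volume_fraction"] = float(volumes[bulk] / volumes.sum())

    ordered = {k: out[k] for k in DISSEMINATION_NAMES}
    assert len(ordered) == 18
    return ordered
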