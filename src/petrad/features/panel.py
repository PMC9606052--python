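"""Full feature-panel extraction per lesion and per patient-level VOI."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..image import SuvImage
from .conventional import CONVENTIONAL_NAMES, conventional_pet
from .intensity import intensity_features
from .morphology import morphology_features
from .resample import discretize, resample
from .texture import TexturePanelConfig, texture_features

__all__ = ["FeatureVector", "extract_panel", "PANEL_COUNTS", "radiomics_names"]

PANEL_COUNTS = {"conventional": 5, "morphology": 22, "intensity": 50, "texture": 408}
_PREFIX = {"conventional": "conv", "morphology": "morph", "intensity": "int",
           "texture": "tex", "dissemination": "diss"}


@dataclass
class FeatureVector:
    """Ordered named feature values with category tags."""

    names: list[str]
    categories: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate feature names")
        if not (len(self.names) == len(self.categories) == len(self.values)):
            raise ValueError("names/categories/values length mismatch")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.categories:
            out[c] = out.get(c, 0) + 1
        return out

    def subset(self, category: str) -> "FeatureVector":
        keep = [k for k, c in enumerate(self.categories) if c == category]
        return FeatureVector([self.names[k] for k in keep],
                             [self.categories[k] for k in keep],
                             self.values[keep])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def _assemble(parts: list[tuple[str, dict[str, float]]]) -> FeatureVector:
    names, cats, vals = [], [], []
    for category, feats in parts:
        for name, value in feats.items():
            names.append(f"{_PREFIX[category]}_{name}")
            cats.append(category)
            vals.append(value)
    return FeatureVector(names, cats, np.asarray(vals))


def _crop_with_margin(image: SuvImage, mask: np.ndarray, margin_mm: float = 8.0):
    idx = np.argwhere(mask)
    m = np.ceil(margin_mm / np.asarray(image.spacing)).astype(int)
    lo = np.maximum(idx.min(axis=0) - m, 0)
    hi = np.minimum(idx.max(axis=0) + m + 1, image.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return image.crop(lo, hi), mask[sl]


def extract_single_voi(image: SuvImage, mask: np.ndarray,
                       spacing=(2.0, 2.0, 2.0), bin_width: float = 0.25,
                       panel: TexturePanelConfig | None = None) -> FeatureVector:
    """The 485-feature panel for one VOI (a lesion or a multi-lesion union).

    Conventional PET features are computed on the original grid; morphology,
    intensity and texture on the VOI resampled to 2 mm isotropic voxels and
    discretized at a fixed 0.25 SUV bin width anchored at 0.
    """
    conv = conventional_pet(image, mask)
    sub_img, sub_mask = _crop_with_margin(image, mask)
    res = resample(sub_img, sub_mask, spacing=spacing)
    disc = discretize(res, bin_width=bin_width, anchor=0.0)
    vec = _assemble([
        ("conventional", conv),
        ("morphology", morphology_features(res)),
        ("intensity", intensity_features(res, disc)),
        ("texture", texture_features(disc, panel)),
    ])
    counts = vec.category_counts()
    assert all(counts[c] == n for c, n in PANEL_COUNTS.items()), counts
    return vec


def extract_panel(image: SuvImage, lesions, level: str = "per_lesion",
                  **kwargs):
    """Extract the 485-feature panel.

    ``level='per_lesion'`` returns one FeatureVector per lesion (label order);
    ``level='patient_voi'`` returns a single vector where all lesion voxels
    are processed as one (possibly disconnected) VOI.  In both cases the
    conventional features describe the masked voxels of the original grid.
    """
    if lesions.n_lesions < 1:
        raise ValueError("no lesions to extract features from")
    if level == "per_lesion":
        return [extract_single_voi(image, lesions.mask(les.label), **kwargs)
                for les in lesions.lesions]
    if level == "patient_voi":
        return extract_single_voi(image, lesions.mask(), **kwargs)
    raise ValueError(f"unknown level {level!r}")


def radiomics_names(vec: FeatureVector) -> list[str]:
    """Names of the 480 non-conventional radiomics features, panel order."""
    return [n for n, c in zip(vec.names, vec.categories) if c != "conventional"]
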