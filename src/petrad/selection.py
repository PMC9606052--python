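"""Lesion-selection approaches and feature-table assembly.

Twelve approaches decide which features represent a patient:

========================  ====================================================
``reference``             MTV, SUVpeak, Dmax_bulk (3 columns)
``largest``               radiomics of the largest lesion + conventional (485)
``hottest``               radiomics of the hottest (highest SUVmax) lesion (485)
``patient_mtv``           radiomics of the patient-level VOI (485)
``maximum`` / ``median``  elementwise max / median of per-lesion radiomics (485)
``dissemination``         18 dissemination + 5 conventional (23)
``diss_patient_mtv`` ...  dissemination + one of the four 480-feature sets (503)
========================  ====================================================

Conventional PET features are always the patient-level values (computed on
the union VOI of the original grid), matching the convention that every
approach carries the same five conventional features.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dissemination import dissemination_features
from .features.conventional import CONVENTIONAL_NAMES
from .features.panel import FeatureVector, extract_single_voi
from .phantom import CohortPatient
from .segmentation import LesionSet, add_lesion, delineate

__all__ = [
    "APPROACHES", "ModelSpec", "FeatureTable", "PatientFeatures",
    "select_largest", "select_hottest", "aggregate", "build_feature_table",
    "lesion_concordance", "extract_cohort_features",
]

APPROACHES = [
    "reference", "largest", "hottest", "patient_mtv", "maximum", "median",
    "dissemination", "diss_patient_mtv", "diss_largest", "diss_hottest",
    "diss_maximum", "diss_median",
]
REDUCTIONS = ["none", "pca", "fa", "rfe_rf", "rfe_svm", "rfe_lr", "anova_top10pct"]
OVERSAMPLING = ["none", "interpolate"]

#: expected feature-column count per approach
EXPECTED_COLUMNS = {
    "reference": 3,
    "largest": 485, "hottest": 485, "patient_mtv": 485,
    "maximum": 485, "median": 485,
    "dissemination": 23,
    "diss_patient_mtv": 503, "diss_largest": 503, "diss_hottest": 503,
    "diss_maximum": 503, "diss_median": 503,
}


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the experiment grid: approach x oversampling x reduction."""

    approach_id: str
    oversampling: str = "none"
    reduction: str = "none"

    def __post_init__(self) -> None:
        if self.approach_id not in APPROACHES:
            raise ValueError(f"unknown approach {self.approach_id!r}; valid: {APPROACHES}")
        if self.oversampling not in OVERSAMPLING:
            raise ValueError(f"oversampling must be one of {OVERSAMPLING}")
        if self.reduction not in REDUCTIONS:
            raise ValueError(f"reduction must be one of {REDUCTIONS}")

    @property
    def n_expected_columns(self) -> int:
        return EXPECTED_COLUMNS[self.approach_id]


@dataclass
class FeatureTable:
    """Patients x features matrix with ids and binary outcome."""

    patient_ids: list[int]
    X: pd.DataFrame
    y: np.ndarray
    approach_id: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        if len(self.X) != len(self.y):
            raise ValueError("X/y length mismatch")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def has_both_classes(self) -> bool:
        return 0 < self.y.sum() < len(self.y)


def select_largest(lesions: LesionSet) -> int:
    """Label of the largest-volume lesion (labels are volume-ordered)."""
    if lesions.n_lesions < 1:
        raise ValueError("empty lesion set")
    return max(lesions.lesions, key=lambda l: (l.volume_ml, -l.label)).label


def select_hottest(lesions: LesionSet) -> int:
    """Label of the hottest lesion (max SUVmax; ties by volume then label)."""
    if lesions.n_lesions < 1:
        raise ValueError("empty lesion set")
    return max(lesions.lesions, key=lambda l: (l.suv_max, l.volume_ml, -l.label)).label


def aggregate(per_lesion_vectors: list[FeatureVector], how: str) -> FeatureVector:
    """Elementwise ``maximum`` or ``median`` of per-lesion radiomics features.

    Applies to the 480 non-conventional features; conventional PET features
    are taken at patient level by the table builder.
    """
    if how not in ("maximum", "median"):
        raise ValueError("how must be 'maximum' or 'median'")
    if not per_lesion_vectors:
        raise ValueError("need at least one lesion vector")
    names0 = per_lesion_vectors[0].names
    for v in per_lesion_vectors[1:]:
        if v.names != names0:
            raise ValueError("feature-name mismatch across lesions")
    keep = [k for k, c in enumerate(per_lesion_vectors[0].categories)
            if c != "conventional"]
    stack = np.stack([v.values[keep] for v in per_lesion_vectors])
    agg = stack.max(axis=0) if how == "maximum" else np.median(stack, axis=0)
    return FeatureVector([names0[k] for k in keep],
                         [per_lesion_vectors[0].categories[k] for k in keep], agg)


@dataclass
class PatientFeatures:
    """All extracted feature sources for one patient."""

    patient_id: int
    outcome: int
    conventional: dict[str, float]            # patient-level, original grid
    dissemination: dict[str, float]
    lesions: LesionSet
    per_lesion: list[FeatureVector] | None = None   # label order
    patient_voi: FeatureVector | None = None


def _needs(approaches) -> tuple[bool, bool]:
    per_lesion = any(a in ("largest", "hottest", "maximum", "median",
                           "diss_largest", "diss_hottest", "diss_maximum",
                           "diss_median") for a in approaches)
    patient = any(a in ("patient_mtv", "diss_patient_mtv") for a in approaches)
    return per_lesion, patient


def segment_patient(image, suv_threshold: float = 4.0,
                    min_volume_ml: float = 3.0) -> LesionSet:
    """Delineate; if the volume filter leaves nothing, emulate the manual
    single-click addition of the small lesion at the hottest voxel."""
    lesions = delineate(image, suv_threshold, min_volume_ml)
    if lesions.n_lesions == 0 and (image.data >= suv_threshold).any():
        seed = np.unravel_index(int(np.argmax(image.data)), image.shape)
        lesions = add_lesion(lesions, image, seed, suv_threshold)
    return lesions


def extract_cohort_features(patients: list[CohortPatient],
                            approaches=None,
                            suv_threshold: float = 4.0,
                            min_volume_ml: float = 3.0) -> list[PatientFeatures]:
    """Segment every patient and extract only the feature sources the
    requested approaches need (full panels are the expensive part)."""
    if approaches is None:
        approaches = APPROACHES
    need_lesion, need_patient = _needs(approaches)
    from .features.conventional import conventional_pet

    out = []
    for pat in patients:
        lesions = segment_patient(pat.image, suv_threshold, min_volume_ml)
        if lesions.n_lesions == 0:
            warnings.warn(f"patient {pat.patient_id}: no lesion above threshold; skipped")
            continue
        conv = conventional_pet(pat.image, lesions.mask())
        diss = dissemination_features(lesions)
        pf = PatientFeatures(pat.patient_id, pat.outcome, conv, diss, lesions)
        if need_lesion:
            pf.per_lesion = [extract_single_voi(pat.image, lesions.mask(l.label))
                             for l in lesions.lesions]
        if need_patient:
            pf.patient_voi = extract_single_voi(pat.image, lesions.mask())
        out.append(pf)
    return out


def _radiomics_row(pf: PatientFeatures, approach: str) -> pd.Series:
    if approach in ("largest", "diss_largest"):
        vec = pf.per_lesion[select_largest(pf.lesions) - 1]
        keep = [k for k, c in enumerate(vec.categories) if c != "conventional"]
        return pd.Series(vec.values[keep], index=[vec.names[k] for k in keep])
    if approach in ("hottest", "diss_hottest"):
        vec = pf.per_lesion[select_hottest(pf.lesions) - 1]
        keep = [k for k, c in enumerate(vec.categories) if c != "conventional"]
        return pd.Series(vec.values[keep], index=[vec.names[k] for k in keep])
    if approach in ("patient_mtv", "diss_patient_mtv"):
        vec = pf.patient_voi
        keep = [k for k, c in enumerate(vec.categories) if c != "conventional"]
        return pd.Series(vec.values[keep], index=[vec.names[k] for k in keep])
    if approach in ("maximum", "diss_maximum"):
        return aggregate(pf.per_lesion, "maximum").to_series()
    if approach in ("median", "diss_median"):
        return aggregate(pf.per_lesion, "median").to_series()
    raise ValueError(approach)


def build_feature_table(cohort_features: list[PatientFeatures],
                        spec: ModelSpec) -> FeatureTable:
    """Assemble the patients x features matrix for one approach.

    Column counts are contract-checked: 3 (reference), 485 (single-source
    radiomics), 23 (dissemination) or 503 (dissemination + radiomics).
    """
    a = spec.approach_id
    rows = []
    for pf in cohort_features:
        parts: list[pd.Series] = []
        if a == "reference":
            parts.append(pd.Series({
                "conv_mtv_ml": pf.conventional["mtv_ml"],
                "conv_suv_peak": pf.conventional["suv_peak"],
                "diss_dmax_bulk_mm": pf.dissemination["dmax_bulk_mm"],
            }))
        else:
            if a.startswith("diss") or a == "dissemination":
                parts.append(pd.Series({f"diss_{k}": v for k, v in pf.dissemination.items()}))
            if a != "dissemination":
                missing = []
                if a in ("patient_mtv", "diss_patient_mtv") and pf.patient_voi is None:
                    missing.append("patient_voi panel")
                if a not in ("patient_mtv", "diss_patient_mtv") and pf.per_lesion is None:
                    missing.append("per-lesion panels")
                if missing:
                    raise ValueError(f"missing feature source for approach {a!r}: "
                                     f"{missing} (patient {pf.patient_id})")
                parts.append(_radiomics_row(pf, a))
            parts.append(pd.Series({f"conv_{k}": v for k, v in pf.conventional.items()}))
        rows.append(pd.concat(parts))
    X = pd.DataFrame(rows).reset_index(drop=True)
    expected = spec.n_expected_columns
    if X.shape[1] != expected:
        raise AssertionError(f"approach {a}: {X.shape[1]} columns, expected {expected}")
    return FeatureTable(
        patient_ids=[pf.patient_id for pf in cohort_features],
        X=X,
        y=np.array([pf.outcome for pf in cohort_features]),
        approach_id=a,
    )


def lesion_concordance(lesion_sets: list[LesionSet]):
    """Fraction of patients whose largest and hottest lesions coincide.

    Returns ``(fraction, breakdown)`` where the breakdown partitions the
    mismatching patients: largest lesion < 10 mL, else largest lesion
    SUVpeak < 10, else other.
    """
    if any(ls.n_lesions < 1 for ls in lesion_sets):
        raise ValueError("every patient needs at least one lesion")
    n_match = 0
    breakdown = {"largest_below_10ml": 0, "largest_suv_peak_below_10": 0, "other": 0}
    for ls in lesion_sets:
        largest = select_largest(ls)
        if largest == select_hottest(ls):
            n_match += 1
            continue
        big = next(l for l in ls.lesions if l.label == largest)
        if big.volume_ml < 10.0:
            breakdown["largest_below_10ml"] += 1
        elif big.suv_peak < 10.0:
            breakdown["largest_suv_peak_below_10"] += 1
        else:
            breakdown["other"] += 1
    return n_match / len(lesion_sets), breakdown
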