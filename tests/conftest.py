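"""Shared fixtures: compact phantom cohorts with full feature extraction.

The synthetic study conditions used in tests are scaled-down cohorts on
48x48x64-voxel grids (2 mm isotropic) with 1-4 lesions of 9-16 mm radius
(3-17 mL) and peak SUVs of 4.5-25; see docs/methods.md for the rationale.
Expensive extractions are session-scoped and shared across test modules.
"""
from __future__ import annotations

import numpy as np
import pytest

from petrad.image import SuvImage
from petrad.phantom import CohortConfig, PhantomConfig, generate_cohort
from petrad.selection import APPROACHES, ModelSpec, build_feature_table, \
    extract_cohort_features


def small_phantom(**overrides) -> PhantomConfig:
    kwargs = dict(
        grid_shape=(48, 48, 64),
        spacing=(2.0, 2.0, 2.0),
        n_lesions_range=(1, 4),
        lesion_radius_range_mm=(9.0, 16.0),
        lesion_suv_range=(4.5, 25.0),
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


def sphere_image(radius_mm=10.0, peak=8.0, shape=(40, 40, 40), spacing=(2, 2, 2),
                 background=1.0, center=None):
    from petrad.phantom import render_lesion

    img = SuvImage(np.full(shape, background), spacing)
    if center is None:
        # align the center with a voxel center: keeps lattice discretization
        # of the sphere volume unbiased
        center = tuple(np.round((np.asarray(shape) - 1) / 2.0) * np.asarray(spacing))
    render_lesion(img, center, radius_mm, peak, background_suv=background)
    return img, center


@pytest.fixture(scope="session")
def phantom_small():
    return small_phantom()


@pytest.fixture(scope="session")
def cohort150(phantom_small):
    """150-patient cohort used for modeling calibration checks."""
    cfg = CohortConfig(n_patients=150, seed=11)
    return generate_cohort(cfg, phantom_small, n_pilot=4000)


@pytest.fixture(scope="session")
def cohort150_features(cohort150):
    """Full feature extraction (per-lesion + patient VOI panels) for all approaches."""
    return extract_cohort_features(cohort150, approaches=APPROACHES)


@pytest.fixture(scope="session")
def tables150(cohort150_features):
    return {a: build_feature_table(cohort150_features, ModelSpec(a))
            for a in APPROACHES}


@pytest.fixture(scope="session")
def mini_features():
    """A 30-patient cohort with only the cheap feature sources (no texture)."""
    cfg = CohortConfig(n_patients=30, seed=23)
    patients = generate_cohort(cfg, small_phantom(), n_pilot=2000)
    return extract_cohort_features(patients, approaches=["reference", "dissemination"])
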