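"""Phantom generator: rendering geometry, determinism, outcome calibration."""
import numpy as np
import pytest

from petrad.image import SuvImage
from petrad.phantom import (CohortConfig, PhantomConfig, _calibration,
                            _pilot_seed, _sample_lesions, bayes_auc,
                            generate_cohort, generate_patient, render_lesion)

from conftest import small_phantom, sphere_image


class TestRenderLesion:
    def test_sphere_volume_matches_analytic(self):
        # r = 6.2 mm sphere -> 4/3*pi*r^3 ~ 998 mm^3, within one voxel volume
        img, _ = sphere_image(radius_mm=6.2, peak=8.0)
        vol_mm3 = (img.data >= 4.0).sum() * 8.0
        assert abs(vol_mm3 - 4 / 3 * np.pi * 6.2**3) <= 2 * 8.0

    @pytest.mark.parametrize("radius,peak", [(10.0, 8.0), (6.2, 40.0), (8.0, 4.5)])
    def test_thresholded_volume_within_5pct(self, radius, peak):
        # the SUV-4.0 iso-contour is pinned at the nominal boundary for any peak
        img, _ = sphere_image(radius_mm=radius, peak=peak)
        vol = (img.data >= 4.0).sum() * img.voxel_volume_ml
        analytic = 4 / 3 * np.pi * radius**3 / 1000.0
        assert abs(vol / analytic - 1) < 0.05

    def test_peak_equal_background_is_identity(self):
        img = SuvImage(np.full((30, 30, 30), 1.0), (2, 2, 2))
        before = img.data.copy()
        render_lesion(img, (30, 30, 30), 8.0, 1.0, background_suv=1.0)
        assert np.array_equal(before, img.data)

    def test_disjoint_spheres_are_additive(self):
        img = SuvImage(np.full((60, 30, 30), 1.0), (2, 2, 2))
        render_lesion(img, (24, 30, 30), 8.0, 8.0)
        n1 = (img.data >= 4.0).sum()
        render_lesion(img, (90, 30, 30), 8.0, 8.0)
        assert (img.data >= 4.0).sum() == 2 * n1

    def test_out_of_grid_lesion_names_center(self):
        img = SuvImage(np.full((20, 20, 20), 1.0), (2, 2, 2))
        with pytest.raises(ValueError, match="2.0"):
            render_lesion(img, (2.0, 20.0, 20.0), 10.0, 8.0)


class TestGeneratePatient:
    def test_forced_lesion_count_and_determinism(self):
        cfg = small_phantom(n_lesions_range=(3, 3))
        img1, gt1 = generate_patient(cfg, seed=4)
        img2, gt2 = generate_patient(cfg, seed=4)
        assert len(gt1.lesions) == 3
        assert np.array_equal(img1.data, img2.data)

    def test_max_voxel_reaches_peak(self):
        cfg = small_phantom(lesion_suv_range=(8.0, 8.0))
        img, gt = generate_patient(cfg, seed=1)
        assert img.data.max() >= 8.0 - 0.5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(lesion_suv_range=(3.0, 10.0))  # below SUV threshold
        with pytest.raises(ValueError):
            PhantomConfig(n_lesions_range=(0, 3))
        with pytest.raises(ValueError):
            PhantomConfig(spacing=(2, -2, 2))

    def test_impossible_placement_errors(self):
        cfg = small_phantom(grid_shape=(24, 24, 24), n_lesions_range=(20, 20),
                            lesion_radius_range_mm=(14.0, 16.0))
        with pytest.raises(RuntimeError, match="place"):
            generate_patient(cfg, seed=0)


class TestOutcomeLink:
    def test_prevalence_calibration_over_100_seeds(self, phantom_small):
        """Mean empirical prevalence of 296-patient draws stays within 0.02
        of the 52/296 target when the intercept is pilot-calibrated."""
        cohort = CohortConfig(n_patients=296, seed=0)
        mu, sd, b0, _ = _calibration(cohort, phantom_small, n_pilot=4000)
        coef = np.asarray(cohort.outcome_link_coefficients)
        prevs = []
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            feats = np.array([
                [np.log(sum(l.volume_ml for l in les)),
                 max(l.peak_suv for l in les),
                 _dmax_bulk(les)]
                for les in (_sample_lesions(rng, phantom_small) for _ in range(296))
            ])
            p = 1 / (1 + np.exp(-(b0 + ((feats - mu) / sd) @ coef)))
            prevs.append((rng.uniform(size=296) < p).mean())
        assert abs(np.mean(prevs) - 52 / 296) < 0.02

    def test_zero_coefficients_give_flat_probabilities(self, phantom_small):
        cohort = CohortConfig(n_patients=40, seed=2,
                              outcome_link_coefficients=(0.0, 0.0, 0.0))
        patients = generate_cohort(cohort, phantom_small, n_pilot=1000)
        probs = {round(p.truth.outcome_prob, 12) for p in patients}
        assert len(probs) == 1

    def test_mtv_coefficient_gives_mtv_risk_gradient(self, phantom_small):
        """Monte-Carlo sign check: with a pure log-MTV link, above-median-MTV
        patients must have a higher mean event probability."""
        cohort = CohortConfig(seed=3, outcome_link_coefficients=(1.0, 0.0, 0.0))
        mu, sd, b0, eta = _calibration(cohort, phantom_small, n_pilot=10_000)
        p = 1 / (1 + np.exp(-(b0 + eta)))
        logmtv_z = eta  # with coefficients (1,0,0), eta IS standardized log MTV
        hi = p[logmtv_z > np.median(logmtv_z)].mean()
        lo = p[logmtv_z <= np.median(logmtv_z)].mean()
        assert hi > lo

    def test_bayes_auc_monotone_in_coefficient_scale(self, phantom_small):
        aucs = [bayes_auc(CohortConfig(outcome_link_coefficients=(s * 0.8, s * 0.4, s * 0.5)),
                          phantom_small, n_draws=4000) for s in (0.5, 1.0, 2.0)]
        assert aucs[0] < aucs[1] < aucs[2]
        assert bayes_auc(CohortConfig(outcome_link_coefficients=(0, 0, 0)),
                         phantom_small, n_draws=4000) == pytest.approx(0.5, abs=1e-9)

    def test_cohort_determinism_and_pfs_mode(self, phantom_small):
        cc = CohortConfig(n_patients=12, seed=9)
        a = generate_cohort(cc, phantom_small, n_pilot=500)
        b = generate_cohort(cc, phantom_small, n_pilot=500)
        assert [p.outcome for p in a] == [p.outcome for p in b]
        assert np.array_equal(a[3].image.data, b[3].image.data)
        pfs = CohortConfig(n_patients=12, seed=9, endpoint_mode="pfs")
        c = generate_cohort(pfs, phantom_small, n_pilot=500)
        assert all(cp.truth.outcome_prob >= ap.truth.outcome_prob - 1e-12
                   for cp, ap in zip(c, a))


def _dmax_bulk(lesions):
    centers = np.array([l.center_mm for l in lesions])
    bulk = int(np.argmax([l.volume_ml for l in lesions]))
    return float(np.linalg.norm(centers - centers[bulk], axis=1).max()) if len(lesions) > 1 else 0.0
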