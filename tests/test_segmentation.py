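"""Delineation: threshold/volume rules, mask editing, QC, oracle equivalence."""
import numpy as np
import pytest

import oracles as O
from petrad.image import SuvImage
from petrad.phantom import generate_patient, render_lesion
from petrad.segmentation import (add_lesion, check_scan_quality, delineate,
                                 remove_region)

from conftest import small_phantom, sphere_image


def _blob_image(volumes_ml, suvs, centers, shape=(60, 40, 40)):
    img = SuvImage(np.full(shape, 1.0), (2, 2, 2))
    for v, s, c in zip(volumes_ml, suvs, centers):
        r = (3 * v * 1000 / (4 * np.pi)) ** (1 / 3)
        render_lesion(img, c, r, s)
    return img


class TestDelineate:
    def test_single_5ml_blob(self):
        img = _blob_image([5.0], [8.0], [(60, 40, 40)])
        ls = delineate(img)
        assert ls.n_lesions == 1
        assert ls.lesions[0].volume_ml == pytest.approx(5.0, abs=0.5)

    def test_small_blob_filtered_then_added_by_click(self):
        img = _blob_image([2.0], [8.0], [(60, 40, 40)])
        assert delineate(img).n_lesions == 0  # below the 3 mL volume filter
        ls = add_lesion(delineate(img), img, (30, 20, 20), 4.0)
        assert ls.n_lesions == 1
        assert ls.lesions[0].volume_ml == pytest.approx(2.0, abs=0.5)

    def test_subthreshold_uptake_ignored(self):
        img = SuvImage(np.full((30, 30, 30), 3.9), (2, 2, 2))
        assert delineate(img).n_lesions == 0

    def test_nonfinite_voxels_error(self):
        img = SuvImage(np.full((10, 10, 10), 1.0), (2, 2, 2))
        img.data[3, 3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            delineate(img)

    def test_labels_ordered_by_decreasing_volume(self):
        img = _blob_image([4.0, 10.0], [8.0, 8.0], [(30, 40, 40), (86, 40, 40)])
        ls = delineate(img)
        vols = [l.volume_ml for l in ls.lesions]
        assert vols == sorted(vols, reverse=True)
        assert [l.label for l in ls.lesions] == [1, 2]

    def test_monotone_in_threshold_and_volume(self):
        img, _ = generate_patient(small_phantom(n_lesions_range=(3, 4)), seed=5)
        base = delineate(img, 4.0, 3.0).n_lesions
        assert delineate(img, 6.0, 3.0).n_lesions <= base
        assert delineate(img, 4.0, 10.0).n_lesions <= base

    def test_matches_flood_fill_oracle_on_random_grids(self):
        """Same component partition and surviving set as a brute-force
        26-connected flood fill, on 100 random <=20^3 grids."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            shape = tuple(rng.integers(6, 21, size=3))
            data = rng.uniform(0, 8, size=shape)
            img = SuvImage(data, (2, 2, 2))
            min_ml = float(rng.uniform(0.0, 0.1))
            ls = delineate(img, 4.0, min_ml)
            zones = O.zones_oracle((data >= 4.0).astype(np.int32), conn3d=True)
            min_vox = min_ml / img.voxel_volume_ml
            surviving = sorted(len(z) for _, _, z in zones if len(z) >= min_vox)
            got = sorted(l.n_voxels for l in ls.lesions)
            assert got == surviving, seed
            # partition check: every label is exactly one oracle zone
            for l in ls.lesions:
                vox = sorted(map(tuple, np.argwhere(ls.label_map == l.label)))
                assert any(vox == z for _, _, z in zones)


class TestMaskEditing:
    def test_add_inside_existing_is_idempotent(self):
        img = _blob_image([5.0], [8.0], [(60, 40, 40)])
        ls = delineate(img)
        ls2 = add_lesion(ls, img, (30, 20, 20), 4.0)
        assert ls2 is ls

    def test_add_at_background_voxel_errors(self):
        img = _blob_image([5.0], [8.0], [(60, 40, 40)])
        with pytest.raises(ValueError, match="threshold"):
            add_lesion(delineate(img), img, (0, 0, 0), 4.0)

    def test_remove_renumbers_and_roundtrips(self):
        img = _blob_image([10.0, 5.0, 4.0], [8.0, 8.0, 8.0],
                          [(24, 40, 40), (60, 40, 40), (96, 40, 40)])
        ls = delineate(img)
        assert ls.n_lesions == 3
        ls2 = remove_region(ls, 2)
        assert ls2.n_lesions == 2
        assert [l.label for l in ls2.lesions] == [1, 2]
        seed_voxel = tuple(np.argwhere(ls.label_map == 2)[0])
        ls3 = add_lesion(ls2, img, seed_voxel, 4.0)
        orig = ls.summary_frame()
        back = ls3.summary_frame()
        assert np.allclose(orig.values, back.values)

    def test_remove_unknown_and_remove_all(self):
        img = _blob_image([5.0], [8.0], [(60, 40, 40)])
        ls = delineate(img)
        with pytest.raises(KeyError):
            remove_region(ls, 7)
        assert remove_region(ls, 1).n_lesions == 0


class TestRecovery:
    def test_lesion_count_recovered_on_200_phantoms(self):
        """All lesions >= 3 mL and SUV >= 8: delineation recovers the exact
        ground-truth count in >= 99% of 200 seeds."""
        cfg = small_phantom(lesion_radius_range_mm=(9.5, 16.0),
                            lesion_suv_range=(8.0, 25.0))
        hits = sum(
            delineate(generate_patient(cfg, seed=s)[0]).n_lesions
            == len(generate_patient(cfg, seed=s)[1].lesions)
            for s in range(200)
        )
        assert hits >= 198


class TestScanQc:
    @pytest.mark.parametrize("hepatic,glucose,activity,verdict", [
        (2.0, 5.0, None, "pass"),
        (3.5, 5.0, 0.60, "pass_by_activity"),
        (3.5, 5.0, 0.90, "fail"),
        (1.0, 5.0, None, "fail"),
        (2.0, 12.0, 0.60, "fail"),
    ])
    def test_verdicts(self, hepatic, glucose, activity, verdict):
        rec = check_scan_quality(hepatic, glucose, activity)
        assert rec.verdict == verdict
        assert rec.reason

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            check_scan_quality(float("nan"), 5.0)
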