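"""Lesion-selection approaches: picks, aggregation, table contracts,
largest/hottest concordance."""
import numpy as np
import pytest

from petrad.features.panel import FeatureVector
from petrad.selection import (APPROACHES, EXPECTED_COLUMNS, ModelSpec,
                              aggregate, build_feature_table,
                              lesion_concordance, select_hottest,
                              select_largest)

from test_dissemination import lesion_set


class TestSelectors:
    def test_largest_and_hottest(self):
        ls = lesion_set([(0, 0, 0), (50, 0, 0)], volumes=[10.0, 5.0],
                        peaks=[12.0, 18.0])
        assert select_largest(ls) == 1     # labels are volume-ordered
        hot = select_hottest(ls)
        assert ls.lesions[hot - 1].suv_max == 18.0

    def test_single_lesion_coincide(self):
        ls = lesion_set([(0, 0, 0)])
        assert select_largest(ls) == select_hottest(ls) == 1

    def test_empty_set_errors(self):
        from petrad.image import SuvImage
        from petrad.segmentation import LesionSet
        empty = LesionSet(SuvImage(np.ones((2, 2, 2)), (2, 2, 2)),
                          np.zeros((2, 2, 2), np.int32))
        with pytest.raises(ValueError):
            select_largest(empty)


def _vec(values, conv=(1.0, 2.0, 3.0, 4.0, 5.0)):
    names = [f"conv_{k}" for k in range(5)] + [f"tex_{k}" for k in range(len(values))]
    cats = ["conventional"] * 5 + ["texture"] * len(values)
    return FeatureVector(names, cats, np.concatenate([conv, values]))


class TestAggregate:
    def test_maximum_and_median(self):
        vecs = [_vec([2.0, 1.0]), _vec([5.0, 0.0]), _vec([3.0, 7.0])]
        mx = aggregate(vecs, "maximum")
        md = aggregate(vecs, "median")
        assert mx.values.tolist() == [5.0, 7.0]
        assert md.values.tolist() == [3.0, 1.0]
        assert "conventional" not in mx.categories

    def test_single_lesion_identity(self):
        v = _vec([4.0, 2.0])
        agg = aggregate([v], "median")
        assert agg.values.tolist() == [4.0, 2.0]

    def test_name_mismatch_errors(self):
        a = _vec([1.0, 2.0])
        b = FeatureVector(["conv_x", "tex_y"], ["conventional", "texture"],
                          np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="mismatch"):
            aggregate([a, b], "maximum")


class TestFeatureTables:
    def test_column_count_contract_per_approach(self, cohort150_features, tables150):
        for a in APPROACHES:
            assert tables150[a].n_features == EXPECTED_COLUMNS[a]

    def test_reference_columns(self, tables150):
        assert list(tables150["reference"].X.columns) == [
            "conv_mtv_ml", "conv_suv_peak", "diss_dmax_bulk_mm"]

    def test_diss_largest_has_498_radiomics_plus_conv(self, tables150):
        cols = tables150["diss_largest"].X.columns
        assert sum(c.startswith("conv_") for c in cols) == 5
        assert sum(not c.startswith("conv_") for c in cols) == 498

    def test_single_lesion_patients_agree_across_lesion_approaches(
            self, cohort150_features):
        singles = [pf for pf in cohort150_features if pf.lesions.n_lesions == 1]
        assert singles, "fixture should contain single-lesion patients"
        pf = singles[0]
        rows = {}
        for a in ["largest", "hottest", "maximum", "median"]:
            t = build_feature_table([pf], ModelSpec(a))
            rows[a] = t.X.iloc[0]
        for a in ["hottest", "maximum", "median"]:
            assert np.allclose(rows[a].values, rows["largest"].values,
                               equal_nan=False)

    def test_determinism(self, cohort150_features):
        t1 = build_feature_table(cohort150_features[:20], ModelSpec("dissemination"))
        t2 = build_feature_table(cohort150_features[:20], ModelSpec("dissemination"))
        assert t1.X.equals(t2.X)

    def test_missing_source_named_in_error(self, cohort150_features):
        pf = cohort150_features[0]
        import dataclasses
        stripped = dataclasses.replace(pf, per_lesion=None)
        with pytest.raises(ValueError, match="per-lesion"):
            build_feature_table([stripped], ModelSpec("largest"))


class TestConcordance:
    def test_all_single_lesion_gives_one(self):
        sets = [lesion_set([(0, 0, 0)]) for _ in range(5)]
        frac, breakdown = lesion_concordance(sets)
        assert frac == 1.0
        assert sum(breakdown.values()) == 0

    def test_constructed_half_match(self):
        match = lesion_set([(0, 0, 0), (50, 0, 0)], volumes=[10, 5], peaks=[18, 12])
        mismatch = lesion_set([(0, 0, 0), (50, 0, 0)], volumes=[10, 5], peaks=[12, 18])
        frac, breakdown = lesion_concordance([match, mismatch])
        assert frac == 0.5
        assert sum(breakdown.values()) == 1

    def test_breakdown_partitions_mismatches(self):
        small = lesion_set([(0, 0, 0), (50, 0, 0)], volumes=[8, 5], peaks=[5, 9])
        low = lesion_set([(0, 0, 0), (50, 0, 0)], volumes=[40, 5], peaks=[6, 9])
        other = lesion_set([(0, 0, 0), (50, 0, 0)], volumes=[40, 5], peaks=[15, 20])
        frac, breakdown = lesion_concordance([small, low, other])
        assert frac == 0.0
        assert breakdown == {"largest_below_10ml": 1,
                             "largest_suv_peak_below_10": 1, "other": 1}

    def test_independent_peaks_give_expected_rate(self):
        """Monte-Carlo: hottest assigned independently of size over 1,000
        synthetic two-lesion patients -> concordance near 0.5."""
        rng = np.random.default_rng(7)
        sets = []
        for _ in range(1000):
            peaks = rng.uniform(5, 30, size=2)
            sets.append(lesion_set([(0, 0, 0), (50, 0, 0)], volumes=[10, 5],
                                   peaks=peaks))
        frac, _ = lesion_concordance(sets)
        assert frac == pytest.approx(0.5, abs=0.05)
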