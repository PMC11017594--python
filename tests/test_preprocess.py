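import numpy as np
import pandas as pd
import pytest

from omicselect.errors import (
    ConfigError,
    MissingTaxonomyError,
    PairingError,
    ValueDomainError,
    ZeroSampleError,
)
from omicselect.io_tables import FeatureTable, StudyDesign, ViewKind
from omicselect.preprocess import (
    TaxonomyMap,
    aggregate_to_genus,
    log_cpm,
    median_normalize,
    paired_difference,
    prevalence_filter,
    relative_abundance,
    remove_feature,
    standardize_columns,
)


def _counts(values, sample_ids=None, feature_ids=None):
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[0])]
    feature_ids = feature_ids or [f"f{j}" for j in range(values.shape[1])]
    return FeatureTable(
        pd.DataFrame(values, index=sample_ids, columns=feature_ids), ViewKind.counts
    )


class TestMedianNormalize:
    def test_definition(self):
        t = _counts([[2.0], [4.0], [6.0]])
        out = median_normalize(t)
        np.testing.assert_allclose(out.values[:, 0], [0.5, 1.0, 1.5])

    def test_all_zero_feature_unchanged(self):
        t = _counts([[0.0, 2.0], [0.0, 4.0], [0.0, 6.0]])
        out = median_normalize(t)
        np.testing.assert_array_equal(out.values[:, 0], 0.0)

    def test_idempotent(self, rng):
        t = _counts(rng.lognormal(size=(7, 5)))
        once = median_normalize(t)
        twice = median_normalize(once)
        np.testing.assert_allclose(once.values, twice.values, rtol=1e-12)

    def test_output_medians_are_one(self, rng):
        t = _counts(rng.lognormal(size=(9, 6)))
        out = median_normalize(t)
        np.testing.assert_allclose(np.median(out.values, axis=0), 1.0, rtol=1e-12)

    def test_negative_values_rejected(self):
        t = FeatureTable(pd.DataFrame([[-1.0]], index=["s"], columns=["f"]))
        with pytest.raises(ValueDomainError):
            median_normalize(t)


class TestRemoveFeature:
    def test_removes_one_column(self):
        t = _counts(np.ones((3, 4)))
        out = remove_feature(t, "f2")
        assert out.n_features == 3 and "f2" not in out.feature_ids
        assert out.sample_ids == t.sample_ids

    def test_remove_twice_errors(self):
        t = _counts(np.ones((3, 4)))
        out = remove_feature(t, "f2")
        with pytest.raises(KeyError):
            remove_feature(out, "f2")

    def test_unknown_id_named_in_error(self):
        t = _counts(np.ones((2, 2)))
        with pytest.raises(KeyError, match="nope"):
            remove_feature(t, "nope")


class TestAggregateToGenus:
    def test_row_sums_preserved(self, rng):
        t = _counts(rng.integers(0, 20, size=(4, 3)).astype(float),
                    feature_ids=["asv1", "asv2", "asv3"])
        tax = TaxonomyMap({"asv1": "gA", "asv2": "gA", "asv3": "gB"})
        out = aggregate_to_genus(t, tax)
        assert out.n_features == 2
        np.testing.assert_allclose(out.values.sum(axis=1), t.values.sum(axis=1))

    def test_single_genus_collapses_to_row_totals(self):
        t = _counts([[1.0, 2.0], [3.0, 4.0]], feature_ids=["a1", "a2"])
        out = aggregate_to_genus(t, TaxonomyMap({"a1": "g", "a2": "g"}))
        np.testing.assert_allclose(out.values[:, 0], [3.0, 7.0])

    def test_unmapped_asv_raises(self):
        t = _counts([[1.0, 2.0]], feature_ids=["a1", "a2"])
        with pytest.raises(MissingTaxonomyError):
            aggregate_to_genus(t, TaxonomyMap({"a1": "g"}))


class TestPrevalenceFilter:
    def test_exact_boundary(self):
        # one feature present in exactly 5 of 36 samples, one in 6
        values = np.zeros((36, 2))
        values[:5, 0] = 1.0
        values[:6, 1] = 1.0
        out = prevalence_filter(_counts(values), min_samples=6)
        assert out.feature_ids == ["f1"]

    def test_min_samples_one_drops_only_all_zero(self):
        values = np.zeros((4, 2))
        values[0, 0] = 3.0
        out = prevalence_filter(_counts(values), min_samples=1)
        assert out.feature_ids == ["f0"]

    def test_min_samples_above_n_raises(self):
        with pytest.raises(ConfigError):
            prevalence_filter(_counts(np.ones((3, 2))), min_samples=4)

    def test_output_prevalence_invariant(self, rng):
        values = (rng.random((20, 15)) < 0.3) * rng.integers(1, 5, (20, 15))
        out = prevalence_filter(_counts(values.astype(float)), min_samples=4)
        assert ((out.values > 0).sum(axis=0) >= 4).all()


class TestRelativeAbundance:
    def test_definition(self):
        out = relative_abundance(_counts([[2.0, 3.0, 5.0]]))
        np.testing.assert_allclose(out.values[0], [0.2, 0.3, 0.5])
        assert out.view_kind == ViewKind.relative_abundance

    def test_single_feature_all_ones(self):
        out = relative_abundance(_counts([[4.0], [7.0]]))
        np.testing.assert_allclose(out.values[:, 0], 1.0)

    def test_zero_row_names_sample(self):
        with pytest.raises(ZeroSampleError, match="s1"):
            relative_abundance(_counts([[1.0, 1.0], [0.0, 0.0]]))


class TestPairedDifference:
    def _table_for(self, design, fill):
        ids = list(design.table["sample_id"])
        values = np.array([[fill[s]] for s in ids], dtype=float)
        return FeatureTable(pd.DataFrame(values, index=ids, columns=["f"]))

    def test_definition(self, paired_design):
        fill = {s: 3.0 for s in paired_design.table["sample_id"]}
        fill["C1_d0"], fill["C1_d10"] = 3.0, 5.0
        out = paired_difference(self._table_for(paired_design, fill), paired_design)
        assert out.data.loc["C1", "f"] == 2.0

    def test_identical_days_all_zero(self, paired_design):
        fill = {s: 1.5 for s in paired_design.table["sample_id"]}
        out = paired_difference(self._table_for(paired_design, fill), paired_design)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_subject_missing_a_day_dropped(self, paired_design):
        fill = {s: 1.0 for s in paired_design.table["sample_id"]}
        table = self._table_for(paired_design, fill)
        table = FeatureTable(table.data.drop(index=["T3_d0"]))
        out = paired_difference(table, paired_design)
        assert out.n_samples == 5 and "T3" not in out.sample_ids

    def test_no_pairs_raises(self, paired_design):
        day0_only = paired_design.table[paired_design.table["day"] == 0]
        ids = list(day0_only["sample_id"])
        table = FeatureTable(
            pd.DataFrame(np.ones((len(ids), 1)), index=ids, columns=["f"])
        )
        with pytest.raises(PairingError):
            paired_difference(table, paired_design)


class TestLogCpm:
    def test_zero_count_maps_to_zero(self):
        out = log_cpm(_counts([[0.0, 10.0]]))
        assert out.values[0, 0] == 0.0

    def test_full_total_closed_form(self):
        out = log_cpm(_counts([[5.0, 0.0]]))
        assert out.values[0, 0] == pytest.approx(np.log2(1e6 + 1))

    def test_depth_invariance(self, rng):
        counts = rng.integers(1, 50, size=(1, 8)).astype(float)
        a = log_cpm(_counts(counts))
        b = log_cpm(_counts(counts * 2))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)


class TestStandardizeColumns:
    def test_hand_computed(self):
        t = _counts([[1.0], [2.0], [3.0]])
        out = standardize_columns(t)
        np.testing.assert_allclose(
            out.values[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4
        )

    def test_constant_feature_zeroed(self):
        t = _counts([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        out = standardize_columns(t)
        np.testing.assert_array_equal(out.values[:, 0], 0.0)

    def test_idempotent(self, rng):
        t = _counts(rng.standard_normal((6, 4)) + 10)
        once = standardize_columns(t)
        twice = standardize_columns(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)
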