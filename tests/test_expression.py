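"""Expression-battery tests: stratified group comparisons, subtype
analyses, prevalence with Fisher tests, feature correlation, and the
ΔCt operations."""

import math

import numpy as np
import pandas as pd
import pytest

from cernaloop import expression as ex
from cernaloop.datatypes import CtTable, ExpressionDataset
from cernaloop.errors import StratificationError, UndefinedResultError


class TestCompareGroups:
    def test_identical_groups_fc_one_p_one(self):
        samples = [f"S{i}" for i in range(6)]
        ann = pd.DataFrame(
            {
                "who_grade": [2] * 6,
                "recurrent": ["yes", "yes", "yes", "no", "no", "no"],
                "meng_subtype": [None] * 6,
                "chr1p_loss": [None] * 6,
                "chr22q_loss": [None] * 6,
                "necrosis": [None] * 6,
                "ki67_index": [np.nan] * 6,
            },
            index=samples,
        )
        vals = pd.DataFrame({"G": [4.0, 5.0, 6.0, 4.0, 5.0, 6.0]}, index=samples).T
        ds = ExpressionDataset(values=vals, annotation=ann)
        res = ex.compare_groups(ds, "G", "recurrent", "yes", "no")
        assert res.fc == pytest.approx(1.0)
        assert res.test.p_value == pytest.approx(1.0)

    def test_stratified_shift_detected(self, small_dataset):
        res = ex.compare_groups(
            small_dataset, "GENE1", "recurrent", "yes", "no", strata={"who_grade": 2}
        )
        assert res.n_case == 2 and res.n_reference == 2
        assert res.fc == pytest.approx(2 ** (8.1 - 6.05))

    def test_label_symmetry(self, small_dataset):
        fwd = ex.compare_groups(
            small_dataset, "GENE1", "recurrent", "yes", "no", strata={"who_grade": 2}
        )
        rev = ex.compare_groups(
            small_dataset, "GENE1", "recurrent", "no", "yes", strata={"who_grade": 2}
        )
        assert rev.fc == pytest.approx(1.0 / fwd.fc)
        assert rev.test.p_value == pytest.approx(fwd.test.p_value)

    def test_empty_group_is_stratification_error(self, small_dataset):
        with pytest.raises(StratificationError, match="who_grade"):
            ex.compare_groups(
                small_dataset, "GENE1", "necrosis", "yes", "no",
                strata={"who_grade": 2},
            )

    def test_unknown_gene_rejected(self, small_dataset):
        with pytest.raises(KeyError):
            ex.compare_groups(small_dataset, "NOPE", "recurrent", "yes", "no")


class TestSubtypes:
    def _dataset(self, shift_c=0.0, n=6, seed=0):
        rng = np.random.default_rng(seed)
        subtypes = ["A"] * n + ["B"] * n + ["C"] * n
        samples = [f"S{i}" for i in range(3 * n)]
        ann = pd.DataFrame(
            {
                "who_grade": [2] * (3 * n),
                "recurrent": ["no"] * (3 * n),
                "meng_subtype": subtypes,
                "chr1p_loss": [None] * (3 * n),
                "chr22q_loss": [None] * (3 * n),
                "necrosis": [None] * (3 * n),
                "ki67_index": [np.nan] * (3 * n),
            },
            index=samples,
        )
        vals = 5.0 + 0.3 * rng.standard_normal(3 * n)
        vals[2 * n:] += shift_c
        ds = ExpressionDataset(
            values=pd.DataFrame({"G": vals}, index=samples).T, annotation=ann
        )
        return ds

    def test_identical_subtypes_global_p_one(self):
        ds = self._dataset()
        ds.values.loc["G"] = 5.0
        res = ex.compare_subtypes(ds, "G")
        assert res.global_test.p_value == 1.0
        assert len(res.pairwise) == 3

    def test_planted_c_shift_dominates_pairwise_ps(self):
        # only C is shifted: both C-involving pairs should beat the null
        # A-vs-B pair, and the global test should reject
        wins = 0
        for seed in range(10):
            ds = self._dataset(shift_c=1.2, seed=seed)
            res = ex.compare_subtypes(ds, "G")
            pair_p = {pair: t.p_value for pair, _, t in res.pairwise}
            ok = (
                pair_p[("A", "C")] < pair_p[("A", "B")]
                and pair_p[("B", "C")] < pair_p[("A", "B")]
                and res.global_test.p_value < 0.05
            )
            wins += ok
        assert wins >= 8

    def test_unsubtyped_samples_excluded(self, small_dataset):
        # grade-agnostic: 7 subtyped of 8 total
        res = ex.compare_subtypes(small_dataset, "GENE2")
        assert res.n_excluded == 1
        assert sum(res.n_per_subtype) == 7


class TestPrevalence:
    def _annotation(self, rec_counts, nrec_counts):
        rows = []
        for subtype, n in rec_counts.items():
            rows += [{"recurrent": "yes", "meng_subtype": subtype}] * n
        for subtype, n in nrec_counts.items():
            rows += [{"recurrent": "no", "meng_subtype": subtype}] * n
        ann = pd.DataFrame(rows, index=[f"S{i}" for i in range(len(rows))])
        for col in ("chr1p_loss", "chr22q_loss", "necrosis"):
            ann[col] = None
        ann["who_grade"] = 2
        ann["ki67_index"] = np.nan
        return ann

    def test_single_subtype_stratum_is_100_percent(self):
        ann = self._annotation({"C": 5}, {"A": 2, "B": 2, "C": 2})
        res = ex.subtype_prevalence(ann)
        assert res.percentages.loc["C", "yes"] == pytest.approx(100.0)

    def test_prevalence_of_dominant_subtype(self):
        # 6 C / 1 B / 0 A among recurrent: C = 85.7%
        ann = self._annotation({"C": 6, "B": 1}, {"A": 4, "B": 5, "C": 3})
        res = ex.subtype_prevalence(ann)
        assert res.percentages.loc["C", "yes"] == pytest.approx(85.7, abs=0.05)

    def test_percentages_sum_to_100_and_margins_match(self):
        ann = self._annotation({"C": 6, "B": 1, "A": 1}, {"A": 4, "B": 5, "C": 3})
        res = ex.subtype_prevalence(ann)
        assert res.percentages.sum(axis=0).tolist() == pytest.approx([100.0, 100.0])
        assert res.counts.sum().sum() == len(ann)
        for (a, b), t in res.fisher.items():
            n_pair = res.counts.loc[[a, b]].to_numpy().sum()
            assert sum(t.n_per_group) == n_pair

    def test_fisher_detects_enrichment(self):
        ann = self._annotation({"C": 10, "A": 1}, {"A": 12, "C": 2, "B": 3})
        res = ex.subtype_prevalence(ann)
        assert res.fisher[("A", "C")].p_value < 0.01


class TestCorrelateFeatures:
    def test_self_correlation_is_one(self, small_dataset):
        res = ex.correlate_features(small_dataset, "GENE1", "GENE1")
        assert res.rho == pytest.approx(1.0)

    def test_gene_vs_annotation_field(self, small_dataset):
        res = ex.correlate_features(small_dataset, "GENE1", "ki67_index")
        assert res.n == 8
        assert res.rho > 0.5  # constructed to rise together

    def test_constant_feature_is_undefined(self, small_dataset):
        ds = small_dataset
        ds.annotation["ki67_index"] = 3.0
        with pytest.raises(UndefinedResultError):
            ex.correlate_features(ds, "GENE1", "ki67_index")

    def test_too_few_pairs_is_undefined(self, small_dataset):
        ds = small_dataset
        ds.annotation.loc[ds.annotation.index[:6], "ki67_index"] = np.nan
        with pytest.raises(UndefinedResultError):
            ex.correlate_features(ds, "GENE1", "ki67_index")


class TestDeltaCt:
    def _table(self):
        ct = pd.DataFrame(
            {
                "brain": [28.4, 25.0, 18.4],
                "liver": [30.0, 26.5, 19.0],
                "heart": [np.nan, 24.0, 18.0],
                "lung": [27.0, np.nan, 17.5],
            },
            index=["circA", "circB", "GAPDH"],
        )
        return CtTable(ct=ct)

    def test_delta_ct_subtraction(self):
        prof = ex.delta_ct(self._table(), "circA")
        assert prof.values["brain"] == pytest.approx(10.0)
        assert set(prof.values.index) == {"brain", "liver", "lung"}

    def test_reference_against_itself_is_zero(self):
        prof = ex.delta_ct(self._table(), "GAPDH")
        assert (prof.values == 0).all()

    def test_missing_reference_assay_rejected(self):
        with pytest.raises(ValueError, match="ACTB"):
            ex.delta_ct(self._table(), "circA", reference="ACTB")

    def test_invariant_to_per_tissue_ct_offset(self):
        t1 = self._table()
        shifted = t1.ct + pd.Series({"brain": 2.0, "liver": -1.0, "heart": 0.5, "lung": 0.0})
        t2 = CtTable(ct=shifted)
        p1 = ex.delta_ct(t1, "circB")
        p2 = ex.delta_ct(t2, "circB")
        pd.testing.assert_series_equal(p1.values, p2.values)

    def test_correlate_assays_shift_invariance(self):
        table = self._table()
        p1 = ex.delta_ct(table, "circA")
        p2 = ex.DeltaCtProfile("shifted", "GAPDH", p1.values + 3.0)
        res = ex.correlate_assays(p1, p2)
        assert res.rho == pytest.approx(1.0)

    def test_correlate_assays_needs_shared_tissues(self):
        table = self._table()
        p1 = ex.delta_ct(table, "circA")
        p2 = ex.DeltaCtProfile("x", "GAPDH", pd.Series({"brain": 1.0, "liver": 2.0}))
        with pytest.raises(UndefinedResultError):
            ex.correlate_assays(p1, p2)
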