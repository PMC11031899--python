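"""Labels, encodings, vocabulary, stratified split, baseline tables."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxbenefit import features as ft
from .conftest import make_patient


class TestAssignLabel:
    @pytest.mark.parametrize(
        "pfs,event,expected",
        [
            (2.0, 1, ft.RESISTANT),
            (6.5, 1, ft.SENSITIVE),
            (7.0, 0, ft.SENSITIVE),
            (2.0, 0, ft.EXCLUDED),   # censored before the resistant threshold
            (4.0, 1, ft.EXCLUDED),   # intermediate PFS
            (4.0, 0, ft.EXCLUDED),
            (3.0, 1, ft.EXCLUDED),   # boundaries are strict
            (6.0, 1, ft.EXCLUDED),
        ],
    )
    def test_decision_rules(self, pfs, event, expected):
        assert ft.assign_label(pfs, event) == expected

    def test_negative_pfs_rejected(self):
        with pytest.raises(ValueError):
            ft.assign_label(-0.1, 1)

    @given(
        pfs=st.lists(st.floats(0, 20), min_size=2, max_size=2).map(sorted),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_monotone_in_pfs(self, pfs):
        order = {ft.RESISTANT: 0, ft.EXCLUDED: 1, ft.SENSITIVE: 2}
        lo, hi = ft.assign_label(pfs[0], 1), ft.assign_label(pfs[1], 1)
        assert order[lo] <= order[hi]


class TestClinicalFeatures:
    def test_direct_encoding(self):
        p = make_patient(age_years=37, sex="male", histology="intestinal",
                         prior_trastuzumab=0, first_line_duration="ge6")
        vec, names = ft.build_clinical_features(p)
        assert list(vec) == [1, 1, 1, 0, 0, 1]
        assert names == ft.CLINICAL_FEATURE_NAMES

    def test_reference_levels(self):
        p = make_patient(age_years=70, sex="female", histology="diffuse",
                         prior_trastuzumab=1, first_line_duration="mid")
        vec, _ = ft.build_clinical_features(p)
        assert list(vec) == [0, 0, 0, 1, 0, 0]

    def test_mixed_histology_folds_into_diffuse(self):
        p = make_patient(histology="mixed")
        vec, _ = ft.build_clinical_features(p)
        assert vec[2] == 0.0

    def test_unknown_category_named_in_error(self):
        p = make_patient(first_line_duration="whatever")
        with pytest.raises(ValueError, match="first_line_duration"):
            ft.build_clinical_features(p)


class TestVocabularyAndMatrix:
    def test_empty_cohort_vocabulary(self):
        assert len(ft.build_variant_vocabulary([])) == 0

    def test_shared_variant_counted_once(self):
        cohort = [
            make_patient("A", variant_ids={"GENE1_SNV"}),
            make_patient("B", variant_ids={"GENE1_SNV", "GENE2_CNV"}),
        ]
        vocab = ft.build_variant_vocabulary(cohort)
        assert vocab.variant_ids == ("GENE1_SNV", "GENE2_CNV")

    def test_ordering_is_patient_order_invariant(self):
        a = make_patient("A", variant_ids={"GENE9_SNV", "GENE1_CNV"})
        b = make_patient("B", variant_ids={"GENE5_SNV"})
        assert (
            ft.build_variant_vocabulary([a, b]).variant_ids
            == ft.build_variant_vocabulary([b, a]).variant_ids
        )

    def test_matrix_roundtrip_and_row_sums(self):
        cohort = [
            make_patient("A", variant_ids={"GENE1_SNV", "GENE3_SNV"}),
            make_patient("B", variant_ids=set()),
            make_patient("C", variant_ids={"GENE3_SNV"}),
        ]
        vocab = ft.build_variant_vocabulary(cohort)
        mat = ft.build_variant_matrix(cohort, vocab)
        assert mat.shape == (3, 2)
        assert list(mat.sum(axis=1)) == [2, 0, 1]
        # reconstructing sets from the matrix recovers the originals
        for row, p in zip(mat, cohort):
            rebuilt = {vocab.variant_ids[j] for j in np.flatnonzero(row)}
            assert rebuilt == set(p.variant_ids)

    def test_out_of_vocabulary_is_error(self):
        cohort = [make_patient("A", variant_ids={"GENE1_SNV"})]
        vocab = ft.VariantVocabulary(("GENE2_SNV",))
        with pytest.raises(KeyError, match="GENE1_SNV"):
            ft.build_variant_matrix(cohort, vocab)


class TestStratifiedSplit:
    def test_study_sizes_288_to_230_58(self):
        labels = np.array([1] * 116 + [0] * 172)
        res = ft.stratified_split(labels, 0.2, seed=0)
        assert len(res.train_indices) == 230
        assert len(res.validation_indices) == 58

    def test_symmetric_small_allocation(self):
        labels = np.array([1] * 5 + [0] * 5)
        res = ft.stratified_split(labels, 0.2, seed=3)
        val = np.array(labels)[list(res.validation_indices)]
        assert len(val) == 2 and val.sum() == 1

    def test_partition_and_seed_behaviour(self):
        labels = np.array([0, 1] * 25)
        a = ft.stratified_split(labels, 0.3, seed=1)
        b = ft.stratified_split(labels, 0.3, seed=1)
        c = ft.stratified_split(labels, 0.3, seed=2)
        assert a == b
        assert set(a.train_indices) | set(a.validation_indices) == set(range(50))
        assert not set(a.train_indices) & set(a.validation_indices)
        assert len(c.validation_indices) == len(a.validation_indices)
        assert c != a

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ft.stratified_split(np.ones(10), 0.2, seed=0)

    def test_class_proportions_exhaustive_small_n(self):
        """|val_pos/val_n - pos/n| <= 1/val_n for every label mix with n <= 12."""
        for n in range(2, 13):
            for n_pos in range(1, n):
                labels = np.array([1] * n_pos + [0] * (n - n_pos))
                res = ft.stratified_split(labels, 0.2, seed=0)
                val = labels[list(res.validation_indices)]
                val_n = len(val)
                assert val_n == int(np.ceil(n * 0.2))
                assert abs(val.sum() / val_n - n_pos / n) <= 1 / val_n + 1e-12


class TestBalanceTestAndTable:
    def test_perfect_balance(self):
        stat, p = ft.categorical_balance_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_statistic(self):
        # n(ad-bc)^2 / (r1 r2 c1 c2) = 60*300^2/810000 = 20/3
        stat, _ = ft.categorical_balance_test([[20, 10], [10, 20]])
        assert stat == pytest.approx(20 / 3)

    def test_row_swap_symmetry(self):
        t = [[5, 9, 11], [7, 6, 12]]
        assert ft.categorical_balance_test(t)[0] == pytest.approx(
            ft.categorical_balance_test(t[::-1])[0]
        )

    def test_fisher_fallback_when_sparse(self):
        from scipy.stats import fisher_exact

        t = [[1, 9], [8, 2]]
        _, p = ft.categorical_balance_test(t)
        assert p == pytest.approx(fisher_exact(np.array(t))[1])

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            ft.categorical_balance_test([[0, 0], [1, 2]])

    @pytest.mark.parametrize(
        "count,total,expected",
        [(48, 288, 16.7), (189, 288, 65.6), (237, 288, 82.3), (44, 93, 47.3), (1, 1, 100.0)],
    )
    def test_percentage_rounding(self, count, total, expected):
        assert ft.percentage(count, total) == expected

    def test_single_patient_summary(self):
        table = ft.summarize_cohort([[make_patient(sex="male")]])
        df = table.table
        row = df[(df.characteristic == "sex") & (df.level == "male")].iloc[0]
        assert row.iloc[2] == 1 and row.iloc[3] == 100.0

    def test_two_group_summary_counts_and_p(self, small_cohort):
        half = len(small_cohort) // 2
        table = ft.summarize_cohort(
            [small_cohort[:half], small_cohort[half:]], ("a", "b")
        )
        df = table.table
        assert "p_value" in df.columns
        for name, subset in (("a", small_cohort[:half]), ("b", small_cohort[half:])):
            sex_counts = df[df.characteristic == "sex"][f"n_{name}"].sum()
            assert sex_counts == len(subset)
        # percentages recompute exactly from counts
        for _, row in df.iterrows():
            for name, subset in (("a", small_cohort[:half]), ("b", small_cohort[half:])):
                assert row[f"pct_{name}"] == ft.percentage(
                    int(row[f"n_{name}"]), len(subset)
                )
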