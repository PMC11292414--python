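"""Quadrant clustering, Q^CNV statistic, integrative prediction, confusion metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from karyoamp.omics import (
    ConfusionReport,
    IntegrativeEcdnaModel,
    OmicsMatrices,
    QScores,
    aberration_overlap,
    assign_quadrant,
    evaluate_confusion,
    find_island_genes,
    integrative_predict,
    q_cnv_cell,
    q_cnv_gene,
    quadrant_matrix,
)
from oracles import interp_percentile, q_cell_brute, q_gene_brute

finite = st.floats(min_value=-50, max_value=50, allow_nan=False)


def _matrices(cnv: np.ndarray, rna: np.ndarray | None = None) -> OmicsMatrices:
    genes = [f"G{i}" for i in range(cnv.shape[0])]
    cells = [f"C{i}" for i in range(cnv.shape[1])]
    if rna is None:
        rna = np.abs(cnv)
    return OmicsMatrices(
        cnv=pd.DataFrame(cnv, index=genes, columns=cells),
        rna=pd.DataFrame(rna, index=genes, columns=cells),
    )


class TestQuadrants:
    @pytest.mark.parametrize(
        "cnv,rna,expected",
        [
            (3.5, 7.5, "I"),
            (2.9, 7.1, "II"),
            (3.0, 7.0, "III"),  # boundary falls to the lower quadrant
            (2.0, 2.0, "III"),
            (4.0, 2.0, "IV"),
            (3.0, 7.5, "II"),
            (3.5, 7.0, "IV"),
        ],
    )
    def test_threshold_rule(self, cnv, rna, expected):
        assert assign_quadrant(cnv, rna) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            assign_quadrant(float("nan"), 1.0)

    @given(finite, finite)
    def test_partition_exhaustive_and_disjoint(self, cnv, rna):
        assert assign_quadrant(cnv, abs(rna)) in ("I", "II", "III", "IV")

    def test_matrix_counts_sum_to_points(self, default_omics):
        m, _, _ = default_omics
        quad = quadrant_matrix(m)
        counts = quad.stack().value_counts()
        assert counts.sum() == m.cnv.size


class TestIslands:
    def test_planted_island_recovered_exactly(self):
        cnv = np.zeros((10, 20))
        rna = np.ones((10, 20))
        cnv[4, :5] = 6.0
        rna[4, :5] = 9.0
        islands = find_island_genes(_matrices(cnv, rna), min_cells=5)
        assert islands == [("G4", [f"C{i}" for i in range(5)])]

    def test_all_zero_matrices_give_empty_list(self):
        assert find_island_genes(_matrices(np.zeros((5, 5)))) == []

    def test_monotone_in_min_cells(self):
        cnv = np.zeros((10, 20))
        rna = np.ones((10, 20))
        cnv[4, :4] = 6.0
        rna[4, :4] = 9.0
        m = _matrices(cnv, rna)
        assert len(find_island_genes(m, min_cells=3)) == 1
        assert find_island_genes(m, min_cells=5) == []

    def test_high_median_gene_excluded(self):
        # a uniformly amplified gene is not an island: population not at origin
        cnv = np.full((3, 10), 6.0)
        rna = np.full((3, 10), 9.0)
        assert find_island_genes(_matrices(cnv, rna)) == []

    def test_empty_matrices_rejected(self):
        with pytest.raises(ValueError):
            OmicsMatrices(cnv=pd.DataFrame(), rna=pd.DataFrame())


class TestQcnv:
    def test_three_cell_example(self):
        cnv = np.array([[1.0, 2.0, 10.0]])
        qs = q_cnv_gene(_matrices(cnv))
        pk = interp_percentile([1.0, 2.0, 10.0], 99.9)
        assert qs.q_gene.iloc[0, 2] == pytest.approx((10.0 - pk) / 1.0)

    def test_constant_gene_is_nonpositive_zero_at_max(self):
        cnv = np.vstack([np.full(6, 2.5), np.random.default_rng(0).normal(size=6)])
        qs = q_cnv_gene(_matrices(cnv))
        row = qs.q_gene.iloc[0]
        assert (row <= 0).all() and row.max() == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        cnv = rng.normal(size=(6, 8))
        m = _matrices(cnv)
        qs = q_cnv_gene(m).q_gene
        perm = rng.permutation(8)
        m2 = _matrices(cnv[:, perm])
        qs2 = q_cnv_gene(m2).q_gene
        np.testing.assert_allclose(qs.to_numpy()[:, perm], qs2.to_numpy())

    def test_cell_variant_extreme_gene(self):
        rng = np.random.default_rng(2)
        cnv = rng.normal(0, 0.3, size=(1000, 3))
        cnv[7, 0] = 9.0
        qs = q_cnv_cell(_matrices(cnv))
        col = qs.q_cell.iloc[:, 0]
        assert col.loc["G7"] > 0
        assert (col.drop("G7") <= 0).all()

    def test_cell_variant_duplicating_genes_halves_score(self):
        rng = np.random.default_rng(3)
        cnv = rng.normal(size=(40, 3))
        m1 = _matrices(cnv)
        m2 = _matrices(np.vstack([cnv, cnv]))
        q1 = q_cnv_cell(m1).q_cell.to_numpy()
        q2 = q_cnv_cell(m2).q_cell.to_numpy()[:40]
        # oracle agreement on both layouts (interpolated percentile shifts
        # slightly under duplication, the counting denominator doubles)
        np.testing.assert_allclose(q1, q_cell_brute(cnv), atol=1e-12)
        np.testing.assert_allclose(q2, q_cell_brute(np.vstack([cnv, cnv]))[:40], atol=1e-12)

    def test_single_gene_cell_line_is_zero_with_unit_denominator(self):
        cnv = np.array([[1.0, 4.0]])
        qs = q_cnv_cell(_matrices(cnv))
        assert (qs.q_cell.to_numpy() == 0).all()

    def test_gene_variant_needs_two_cells(self):
        with pytest.raises(ValueError):
            q_cnv_gene(_matrices(np.array([[1.0]])))

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_agreement_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        cnv = rng.normal(0, 2, size=(50, 50))
        m = _matrices(cnv)
        np.testing.assert_allclose(q_cnv_gene(m).q_gene.to_numpy(), q_gene_brute(cnv), atol=1e-9)
        np.testing.assert_allclose(q_cnv_cell(m).q_cell.to_numpy(), q_cell_brute(cnv), atol=1e-9)


class TestIntegrative:
    def _fit(self, default_omics, flags=None):
        m, pos, _ = default_omics
        if flags is None:
            flags = {c: (c in pos) for c in m.cells}
        return IntegrativeEcdnaModel(m, flags).fit(), pos

    def test_all_criteria_conjunction(self, default_omics):
        res, pos = self._fit(default_omics)
        df = res.to_frame()
        called = df[df["status"] == "positive"]
        assert (called[["q_gene_pass", "q_cell_pass", "quadrant_I", "external"]].all(axis=1)).all()

    def test_external_flag_false_blocks_positive(self, default_omics):
        m, pos, _ = default_omics
        res = IntegrativeEcdnaModel(m, {c: False for c in m.cells}).fit()
        df = res.to_frame()
        assert (df["status"] == "negative").all()
        # evidence breakdown still reports the quadrant-I genes
        assert df.loc[sorted(pos), "quadrant_I"].all()

    def test_missing_flags_reported_not_silently_negative(self, default_omics):
        m, pos, _ = default_omics
        flags = {c: (c in pos) for c in list(m.cells)[:-3]}
        res = IntegrativeEcdnaModel(m, flags).fit()
        df = res.to_frame()
        assert (df.loc[list(m.cells)[-3:], "status"] == "not-evaluable").all()

    def test_monotone_in_evidence(self, default_omics):
        # flipping an external flag to True never flips positive -> negative
        m, pos, _ = default_omics
        base_flags = {c: (c in pos) for c in m.cells}
        res1 = IntegrativeEcdnaModel(m, base_flags).fit()
        res2 = IntegrativeEcdnaModel(m, {c: True for c in m.cells}).fit()
        assert set(res1.positive_cells) <= set(res2.positive_cells)

    def test_requires_both_score_layers(self):
        with pytest.raises(ValueError):
            integrative_predict(QScores(q_gene=pd.DataFrame([[0.0]])), pd.DataFrame(), {})


class TestConfusion:
    def test_hand_computed_instance(self):
        rep = ConfusionReport(tp=2, fp=1, tn=3, fn=2)
        assert rep.accuracy == pytest.approx(0.625)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.f1 == pytest.approx(4 / 7)
        expected_mcc = (2 * 3 - 1 * 2) / np.sqrt((2 + 1) * (2 + 2) * (3 + 1) * (3 + 2))
        assert rep.mcc == pytest.approx(expected_mcc)

    def test_perfect_predictions(self):
        calls = {"a": True, "b": False}
        labels = {"a": "positive", "b": "negative"}
        rep = evaluate_confusion(calls, labels)
        assert rep.accuracy == 1.0 and rep.mcc == 1.0

    def test_all_positive_on_balanced_labels(self):
        calls = {c: True for c in "abcd"}
        labels = {"a": "positive", "b": "positive", "c": "negative", "d": "negative"}
        rep = evaluate_confusion(calls, labels)
        assert rep.precision == 0.5
        assert rep.mcc == 0.0  # zero marginal convention

    def test_unknown_labels_excluded(self):
        calls = {"a": True, "b": True}
        labels = {"a": "positive", "b": "unknown"}
        rep = evaluate_confusion(calls, labels)
        assert rep.n == 1

    def test_nothing_evaluable_rejected(self):
        with pytest.raises(ValueError):
            evaluate_confusion({}, {"a": "unknown"})

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_sklearn_on_random_calls(self, seed):
        from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef, precision_score

        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 2, 40)
        y_pred = rng.integers(0, 2, 40)
        cells = [f"c{i}" for i in range(40)]
        rep = evaluate_confusion(
            dict(zip(cells, map(bool, y_pred))),
            dict(zip(cells, ["positive" if t else "negative" for t in y_true])),
        )
        assert rep.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
        assert rep.precision == pytest.approx(precision_score(y_true, y_pred, zero_division=0))
        assert rep.f1 == pytest.approx(f1_score(y_true, y_pred))
        assert rep.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))


class TestAberrationOverlap:
    def test_in_study_instance(self):
        # 34 predicted chromosomes of which 22 are aberrant in karyotypes
        predicted = {f"chr{i}" for i in range(34)}
        aberrant = {f"chr{i}" for i in range(22)}
        assert aberration_overlap(predicted, aberrant) == pytest.approx(64.7, abs=0.05)

    def test_subset_is_100(self):
        assert aberration_overlap({"1", "2"}, {"1", "2", "3"}) == 100.0

    def test_disjoint_is_0(self):
        assert aberration_overlap({"1"}, {"2"}) == 0.0

    def test_empty_prediction_rejected(self):
        with pytest.raises(ValueError):
            aberration_overlap(set(), {"1"})
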