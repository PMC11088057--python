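"""Relative expression, weighted pathway activity, permutation significance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scmetland as sm
from scmetland import CellAnnotation, ExpressionMatrix, GeneSetCollection
from scmetland.pathway import (
    RelativeExpressionTable,
    flag_outliers,
    pathway_activity_scores,
    permutation_test,
    relative_expression,
)


def _dataset(values, cell_types):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    cells = [f"c{i}" for i in range(values.shape[1])]
    matrix = ExpressionMatrix(values, genes, cells, stage="log2tpm1")
    ann = CellAnnotation(pd.DataFrame({
        "sample_id": "s", "tissue_group": "tumor", "cell_type": cell_types,
    }, index=pd.Index(cells)))
    return matrix, ann


def _oracle_relative(values, cell_types):
    """Independent double-loop recomputation of mean and relative expression."""
    types = sorted(set(cell_types))
    means = np.zeros((values.shape[0], len(types)))
    for gi in range(values.shape[0]):
        for ti, t in enumerate(types):
            cols = [ci for ci, ct in enumerate(cell_types) if ct == t]
            means[gi, ti] = np.mean([values[gi, c] for c in cols])
    rel = np.full_like(means, np.nan)
    for gi in range(values.shape[0]):
        grand = means[gi].mean()
        if grand > 0:
            rel[gi] = means[gi] / grand
    return means, rel


class TestRelativeExpression:
    def test_equal_means_give_r_one(self):
        matrix, ann = _dataset(np.tile([[2.0], [5.0]], (1, 6)), ["A", "A", "B", "B", "C", "C"])
        table = relative_expression(matrix, ann)
        assert np.allclose(table.relative_expression, 1.0)

    def test_two_types_closed_form(self):
        matrix, ann = _dataset([[2.0, 2.0, 0.0, 0.0]], ["A", "A", "B", "B"])
        table = relative_expression(matrix, ann)
        assert np.allclose(table.relative_expression, [[2.0, 0.0]])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 4, (5, 12))
        cell_types = list(rng.choice(["A", "B", "C"], 12))
        cell_types[:3] = ["A", "B", "C"]  # ensure every type present
        matrix, ann = _dataset(values, cell_types)
        table = relative_expression(matrix, ann)
        means, rel = _oracle_relative(values, cell_types)
        assert np.allclose(table.mean_expression, means, atol=1e-12)
        assert np.allclose(table.relative_expression, rel, atol=1e-12, equal_nan=True)

    def test_all_zero_gene_excluded(self):
        matrix, ann = _dataset([[0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 3.0, 3.0]],
                               ["A", "A", "B", "B"])
        table = relative_expression(matrix, ann)
        assert table.excluded_genes == ["g0"]
        assert np.isnan(table.relative_expression[0]).all()

    def test_single_type_is_error(self):
        matrix, ann = _dataset([[1.0, 2.0]], ["A", "A"])
        with pytest.raises(sm.InsufficientDataError):
            relative_expression(matrix, ann)

    def test_relative_rows_average_to_one(self):
        rng = np.random.default_rng(11)
        matrix, ann = _dataset(rng.uniform(0.1, 5, (8, 9)), ["A", "B", "C"] * 3)
        table = relative_expression(matrix, ann)
        assert np.allclose(table.relative_expression.mean(axis=1), 1.0, atol=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=0.1, max_value=100.0), st.integers(0, 7))
    def test_scale_invariance_per_gene(self, c, gene):
        rng = np.random.default_rng(4)
        values = rng.uniform(0.1, 5, (8, 9))
        cell_types = ["A", "B", "C"] * 3
        matrix, ann = _dataset(values, cell_types)
        base = relative_expression(matrix, ann).relative_expression
        scaled = values.copy()
        scaled[gene] *= c
        matrix2, _ = _dataset(scaled, cell_types)
        other = relative_expression(matrix2, ann).relative_expression
        assert np.allclose(base, other, rtol=1e-9)


class TestOutlierFlags:
    def _table(self, rel):
        rel = np.asarray(rel, dtype=float)
        genes = pd.Index([f"g{i}" for i in range(rel.shape[0])])
        return RelativeExpressionTable(
            genes, [f"T{j}" for j in range(rel.shape[1])],
            mean_expression=rel.copy(), relative_expression=rel,
            retained=np.ones(rel.shape[0], dtype=bool),
        )

    def test_constant_r_no_flags(self):
        table = self._table(np.ones((6, 2)))
        sets = GeneSetCollection({"P": tuple(f"g{i}" for i in range(6))})
        flag_outliers(table, sets)
        assert not table.outlier_flags["P"].any()

    def test_extreme_gene_flagged_by_fence_formula(self):
        rng = np.random.default_rng(0)
        rel = np.column_stack([np.append(rng.normal(1.0, 0.02, 20), 50.0)])
        table = self._table(rel)
        sets = GeneSetCollection({"P": tuple(f"g{i}" for i in range(21))})
        flag_outliers(table, sets, k=1.5)
        flags = table.outlier_flags["P"]
        # direct check of the Tukey fence on the member values
        q1, q3 = np.percentile(rel[:, 0], [25, 75])
        hi = q3 + 1.5 * (q3 - q1)
        assert rel[20, 0] > hi
        assert flags[20, 0]
        assert flags.sum() == ((rel[:, 0] < q1 - 1.5 * (q3 - q1)) | (rel[:, 0] > hi)).sum()

    def test_infinite_k_flags_nothing(self):
        rng = np.random.default_rng(1)
        table = self._table(rng.uniform(0, 10, (15, 3)))
        sets = GeneSetCollection({"P": tuple(f"g{i}" for i in range(15))})
        flag_outliers(table, sets, k=np.inf)
        assert not table.outlier_flags["P"].any()


class TestPathwayActivityScores:
    def test_all_r_one_gives_pa_one_any_weights(self):
        rel = np.ones((4, 3))
        genes = pd.Index(["g0", "g1", "g2", "g3"])
        table = RelativeExpressionTable(genes, ["A", "B", "C"], rel.copy(), rel,
                                        np.ones(4, dtype=bool))
        sets = GeneSetCollection({"P1": ("g0", "g1", "g2"), "P2": ("g2", "g3")})
        res = pathway_activity_scores(table, sets, min_genes=1)
        assert np.allclose(res.scores, 1.0)

    def test_single_gene_pathway_equals_gene_r(self):
        rel = np.array([[1.7, 0.3]])
        table = RelativeExpressionTable(pd.Index(["g0"]), ["A", "B"], rel.copy(), rel,
                                        np.ones(1, dtype=bool))
        sets = GeneSetCollection({"P": ("g0",)})
        res = pathway_activity_scores(table, sets, min_genes=1)
        assert np.allclose(res.scores, rel)

    def test_hand_computed_weighted_average(self):
        # r = (2, 1), weights (1, 0.5): PA = (2*1 + 1*0.5) / 1.5 = 5/3
        rel = np.array([[2.0], [1.0], [1.0]])
        table = RelativeExpressionTable(pd.Index(["g0", "g1", "g2"]), ["A"],
                                        rel.copy(), rel, np.ones(3, dtype=bool))
        sets = GeneSetCollection({"P1": ("g0", "g1"), "P2": ("g1", "g2")})
        assert sets.weights == {"g0": 1.0, "g1": 0.5, "g2": 1.0}
        res = pathway_activity_scores(table, sets, min_genes=1)
        i = res.pathways.index("P1")
        assert res.scores[i, 0] == pytest.approx(5.0 / 3.0, abs=1e-12)

    def test_small_pathways_reported_absent(self):
        rel = np.array([[2.0], [1.0]])
        table = RelativeExpressionTable(pd.Index(["g0", "g1"]), ["A"], rel.copy(), rel,
                                        np.ones(2, dtype=bool))
        sets = GeneSetCollection({"P": ("g0", "g1")})
        res = pathway_activity_scores(table, sets, min_genes=5)
        assert np.isnan(res.scores).all()


def _oracle_pa(values, cell_types, members, weights):
    """Independent PA computation: loops, no outlier handling."""
    types = sorted(set(cell_types))
    _, rel = _oracle_relative(values, cell_types)
    out = []
    for ti in range(len(types)):
        num = den = 0.0
        for g, w in zip(members, weights):
            if not np.isnan(rel[g, ti]):
                num += w * rel[g, ti]
                den += w
        out.append(num / den if den else np.nan)
    return np.array(out)


class TestPermutationTest:
    def test_constant_matrix_pvalue_one(self):
        values = np.full((6, 8), 3.0)
        matrix, ann = _dataset(values, ["A", "B"] * 4)
        sets = GeneSetCollection({"P": tuple(f"g{i}" for i in range(6))})
        res = permutation_test(matrix, ann, sets, n_perm=100, seed=0)
        assert np.allclose(res.scores, 1.0)
        assert np.allclose(res.p_values, 1.0)

    def test_pvalues_never_zero_and_in_unit_interval(self, small_null_sim):
        matrix, ann, sets, _ = small_null_sim
        matrix = sm.log_transform(matrix)
        res = permutation_test(matrix, ann, sets, n_perm=100, seed=1)
        p = res.p_values[~np.isnan(res.p_values)]
        assert (p > 0).all() and (p <= 1).all()

    def test_six_cell_toy_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0.5, 3.0, (5, 6))
        cell_types = ["A", "A", "A", "B", "B", "B"]
        matrix, ann = _dataset(values, cell_types)
        sets = GeneSetCollection({"P": tuple(f"g{i}" for i in range(5))})
        members = list(range(5))
        weights = [1.0] * 5

        obs = _oracle_pa(values, cell_types, members, weights)
        count = total = 0
        for labels in set(itertools.permutations(cell_types)):
            pa = _oracle_pa(values, list(labels), members, weights)
            if np.max(np.abs(pa - 1.0)) >= np.max(np.abs(obs - 1.0)) - 1e-12:
                count += 1
            total += 1
        # per-(pathway, type) exact p; the toy is symmetric across types
        p_exact = count / total

        res = permutation_test(matrix, ann, sets, n_perm=5000, seed=2,
                               tukey_k=np.inf, min_genes=1)
        se = np.sqrt(p_exact * (1 - p_exact) / 5000)
        assert res.p_values[0, 0] == pytest.approx(p_exact, abs=max(3 * se, 2e-3))
        assert res.p_values[0, 1] == pytest.approx(p_exact, abs=max(3 * se, 2e-3))

    def test_small_n_perm_rejected(self, tiny_matrix, tiny_sets):
        matrix, ann = tiny_matrix
        with pytest.raises(sm.ConfigError):
            permutation_test(matrix, ann, tiny_sets, n_perm=50)

    def test_deterministic_under_seed(self, tiny_matrix, tiny_sets):
        matrix, ann = tiny_matrix
        r1 = permutation_test(matrix, ann, tiny_sets, n_perm=100, seed=5, min_genes=1)
        r2 = permutation_test(matrix, ann, tiny_sets, n_perm=100, seed=5, min_genes=1)
        assert np.array_equal(r1.p_values, r2.p_values, equal_nan=True)
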