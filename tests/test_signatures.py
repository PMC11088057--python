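"""Per-cell signature scores, correlation by type, tissue-group comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

import scmetland as sm
from scmetland import CellAnnotation, CellSignatureScores, ExpressionMatrix
from scmetland.signatures import compare_groups, correlate_by_type, score_cells


def _matrix(values, stage="imputed"):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    cells = [f"c{i}" for i in range(values.shape[1])]
    imputed = np.zeros(values.shape, dtype=bool) if stage == "imputed" else None
    return ExpressionMatrix(values, genes, cells, stage=stage, imputed=imputed)


def _annotation(cell_types, tissue=None, cells=None):
    n = len(cell_types)
    cells = cells or [f"c{i}" for i in range(n)]
    return CellAnnotation(pd.DataFrame({
        "sample_id": "s",
        "tissue_group": tissue if tissue is not None else ["tumor"] * n,
        "cell_type": cell_types,
    }, index=pd.Index(cells)))


class TestScoreCells:
    def test_single_gene_set_is_that_genes_zscore(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 5, (3, 20))
        matrix = _matrix(values)
        scores = score_cells(matrix, ["g1"])
        x = values[1]
        expected = (x - x.mean()) / x.std()
        assert np.allclose(scores.to_numpy(), expected, atol=1e-12)

    def test_constant_genes_skipped_with_warning(self):
        values = np.vstack([np.full(10, 2.0), np.linspace(0, 5, 10)])
        matrix = _matrix(values)
        with pytest.warns(UserWarning, match="constant"):
            scores = score_cells(matrix, ["g0", "g1"])
        assert scores.attrs["constant_genes"] == ["g0"]
        with pytest.warns(UserWarning), pytest.raises(sm.ValidationError, match="constant"):
            score_cells(matrix, ["g0"])

    def test_no_overlap_is_error(self):
        matrix = _matrix(np.ones((2, 4)))
        with pytest.raises(sm.ValidationError, match="overlap"):
            score_cells(matrix, ["nope"])

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 6, (40, 40))
        matrix = _matrix(values)
        genes = [f"g{i}" for i in range(0, 40, 2)]
        scores = score_cells(matrix, genes)
        # independent two-pass loop
        expected = np.zeros(40)
        for c in range(40):
            acc = []
            for g in genes:
                gi = int(g[1:])
                row = values[gi]
                acc.append((row[c] - row.mean()) / row.std())
            expected[c] = np.mean(acc)
        assert np.allclose(scores.to_numpy(), expected, atol=1e-10)


class TestCorrelateByType:
    def test_identical_scores_give_one(self):
        h = np.linspace(0, 1, 24)
        frame = pd.DataFrame({"hypoxia": h, "glycolysis": h},
                             index=[f"c{i}" for i in range(24)])
        ann = _annotation(["A"] * 12 + ["B"] * 12)
        out = correlate_by_type(CellSignatureScores(frame), ann)
        assert np.allclose(out["r"], 1.0)

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame({"hypoxia": rng.normal(size=1000),
                              "glycolysis": rng.normal(size=1000)},
                             index=[f"c{i}" for i in range(1000)])
        ann = _annotation(["A"] * 1000)
        out = correlate_by_type(CellSignatureScores(frame), ann)
        assert abs(out["r"].iloc[0]) < 0.1

    def test_small_types_reported_absent(self):
        frame = pd.DataFrame({"hypoxia": np.arange(12.0), "glycolysis": np.arange(12.0)},
                             index=[f"c{i}" for i in range(12)])
        ann = _annotation(["A"] * 9 + ["B"] * 3)
        out = correlate_by_type(CellSignatureScores(frame), ann).set_index("cell_type")
        assert np.isnan(out.loc["A", "r"]) and np.isnan(out.loc["B", "r"])

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        h = rng.normal(size=60)
        g = h + rng.normal(scale=0.5, size=60)
        idx = [f"c{i}" for i in range(60)]
        ann = _annotation(["A"] * 60)
        r1 = correlate_by_type(CellSignatureScores(
            pd.DataFrame({"hypoxia": h, "glycolysis": g}, index=idx)), ann)["r"].iloc[0]
        r2 = correlate_by_type(CellSignatureScores(
            pd.DataFrame({"hypoxia": np.exp(h), "glycolysis": g**3}, index=idx)), ann)["r"].iloc[0]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_planted_rho_recovered_per_type(self):
        cfg = sm.SimulationConfig(n_genes=400, n_cells_per_type=(250, 250), n_pathways=8,
                                  hypoxia_rho=0.8, seed=4)
        matrix, ann, gene_sets, _ = sm.simulate(cfg)
        matrix = sm.impute(
            sm.log_transform(matrix),
            sm.PreprocessConfig(imputation="knn_smooth", k_neighbors=10), ann,
        )
        scores = CellSignatureScores.compute(matrix, {
            "hypoxia": gene_sets["HALLMARK_HYPOXIA"],
            "glycolysis": gene_sets["GLYCOLYSIS_GLUCONEOGENESIS"],
        })
        out = correlate_by_type(scores, ann, method="spearman")
        assert np.allclose(out["r"], 0.8, atol=0.1)


class TestCompareGroups:
    def _dataset(self, tumor_vals, normal_vals):
        values = np.concatenate([tumor_vals, normal_vals])[None, :]
        n_t, n_n = len(tumor_vals), len(normal_vals)
        matrix = _matrix(values, stage="tpm")
        ann = _annotation(["A"] * (n_t + n_n), tissue=["tumor"] * n_t + ["normal"] * n_n)
        return matrix, ann

    def test_equal_means_zero_log2fc(self):
        matrix, ann = self._dataset(np.array([1.0, 3.0]), np.array([2.0, 2.0]))
        res = compare_groups(matrix, ann, ["g0"])
        assert res.summary["log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_log2fc(self):
        matrix, ann = self._dataset(np.array([3.0, 3.0]), np.array([1.0, 1.0]))
        res = compare_groups(matrix, ann, ["g0"])
        assert res.summary["log2fc"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_positive_planted_effect_positive_log2fc(self):
        rng = np.random.default_rng(5)
        matrix, ann = self._dataset(rng.uniform(4, 8, 50), rng.uniform(1, 3, 50))
        res = compare_groups(matrix, ann, ["g0"])
        assert res.summary["log2fc"].iloc[0] > 0
        assert res.summary["p_value"].iloc[0] < 0.01

    def test_ranksum_matches_exhaustive_enumeration(self):
        tumor = np.array([5.1, 2.3, 7.7, 4.4])
        normal = np.array([1.2, 3.3, 0.9, 2.8])
        matrix, ann = self._dataset(tumor, normal)
        p_impl = compare_groups(matrix, ann, ["g0"]).summary["p_value"].iloc[0]
        # enumerate all C(8,4)=70 group assignments of the pooled values
        pooled = np.concatenate([tumor, normal])
        ranks = pd.Series(pooled).rank().to_numpy()

        def u_stat(idx):
            r1 = ranks[list(idx)].sum()
            return r1 - 4 * 5 / 2  # U of the "tumor" draw

        mu = 4 * 4 / 2
        u_obs = u_stat(range(4))
        devs = [abs(u_stat(c) - mu) for c in itertools.combinations(range(8), 4)]
        p_exact = np.mean([d >= abs(u_obs - mu) - 1e-12 for d in devs])
        assert p_impl == pytest.approx(p_exact, abs=1e-12)

    def test_absent_gene_reported(self):
        matrix, ann = self._dataset(np.ones(3), np.ones(3))
        res = compare_groups(matrix, ann, ["g0", "nope"])
        assert res.absent == ["nope"]

    def test_dotplot_scaled_means_attain_zero_and_one(self):
        rng = np.random.default_rng(6)
        values = rng.uniform(1, 5, (2, 60))[::1]
        matrix = _matrix(values, stage="tpm")
        ann = _annotation(["A"] * 20 + ["B"] * 20 + ["C"] * 20,
                          tissue=["tumor"] * 30 + ["normal"] * 30)
        res = compare_groups(matrix, ann, ["g0", "g1"])
        for _, sub in res.dotplot.groupby("gene"):
            assert sub["scaled_mean"].min() == pytest.approx(0.0)
            assert sub["scaled_mean"].max() == pytest.approx(1.0)
            assert ((sub["fraction_expressing"] >= 0) & (sub["fraction_expressing"] <= 1)).all()

    def test_missing_group_is_error(self):
        matrix = _matrix(np.ones((1, 4)), stage="tpm")
        ann = _annotation(["A"] * 4)
        with pytest.raises(sm.InsufficientDataError):
            compare_groups(matrix, ann, ["g0"])
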