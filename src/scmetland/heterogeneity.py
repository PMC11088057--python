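"""Metabolic heterogeneity: PCA-loading gene scores and preranked GSEA.

Which genes drive cell-to-cell metabolic variability? PCA is run on the
log2(TPM+1) values of the metabolic genes (imputed entries excluded from
the mean/covariance contributions), and each gene's variability score is
the sum of its absolute loadings over the minimal prefix of variance-
ordered components whose cumulative variance share exceeds 80%. Genes
are ranked by this score (descending, ties broken by gene id) and the
ranked list is fed to a preranked GSEA with the weighted Kolmogorov-
Smirnov running-sum statistic to find pathways enriched among the most
variable genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import CellAnnotation, ExpressionMatrix, GeneSetCollection
from .errors import ConfigError, InsufficientDataError

VARIANCE_THRESHOLD = 0.80


@dataclass
class PcaScoreTable:
    """Per-gene PCA variability scores.

    ``scores[g] = sum_c |loading_{g,c}|`` over the selected components;
    sign-flipping any component leaves the scores unchanged.
    """

    genes: pd.Index
    scores: np.ndarray
    n_components_selected: int
    cumulative_variance: float
    variance_shares: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pca_score": self.scores}, index=self.genes)


@dataclass
class GseaResult:
    """Preranked GSEA output: one row per evaluated set.

    ``table`` columns: set, size, es, nes, p_value, p_adjusted (BH across
    sets), leading_edge (comma-joined gene ids). Sets with no overlap
    with the ranked list are listed in ``absent``.
    """

    table: pd.DataFrame
    absent: list[str]
    n_perm: int
    weight_exponent: float
    seed: int | None


def _masked_covariance(x: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Gene x gene covariance using only observed entries.

    Pairwise-complete convention: the (i, j) covariance averages centred
    products over cells where both genes are observed; per-gene means use
    each gene's own observed cells. Denominator n_ij - 1.
    """
    obs = observed.astype(float)
    counts = obs.sum(axis=1, keepdims=True)
    counts[counts == 0] = 1.0
    means = (x * obs).sum(axis=1, keepdims=True) / counts
    xc = (x - means) * obs
    pair_counts = obs @ obs.T
    denom = np.maximum(pair_counts - 1.0, 1.0)
    return (xc @ xc.T) / denom


def pca_gene_scores(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation | None = None,
    scope: str | None = None,
    genes: list[str] | None = None,
    variance_threshold: float = VARIANCE_THRESHOLD,
    missing: str = "pairwise",
) -> PcaScoreTable:
    """PCA-loading variability score per gene.

    Parameters
    ----------
    scope
        Restrict to cells of one tissue group (``"tumor"``/``"normal"``);
        requires an annotation. ``None`` uses all cells.
    genes
        Restrict to these genes (typically the metabolic genes); absent
        ids are ignored. ``None`` uses all genes.
    missing
        ``"pairwise"`` excludes imputed entries from the per-gene means
        and from each covariance term (pairwise-complete); ``"complete"``
        drops every cell that has any imputed entry among the selected
        genes. With no imputed entries both give the standard covariance.

    The components kept are the minimal prefix of variance-ordered
    components whose cumulative variance share strictly exceeds the
    threshold (the crossing component is included).
    """
    if missing not in ("pairwise", "complete"):
        raise ConfigError("missing must be 'pairwise' or 'complete'")
    values = matrix.values
    mask = matrix.imputed
    cell_sel = np.ones(matrix.n_cells, dtype=bool)
    if scope is not None:
        if annotation is None:
            raise ConfigError("scope requires an annotation")
        ann = annotation.for_matrix(matrix)
        cell_sel = (ann["tissue_group"] == scope).to_numpy()
    if genes is not None:
        gidx = matrix.gene_indexer(genes)
    else:
        gidx = np.arange(matrix.n_genes)
    x = values[np.ix_(gidx, np.where(cell_sel)[0])]
    imputed = mask[np.ix_(gidx, np.where(cell_sel)[0])]

    if missing == "complete" and imputed.any():
        keep = ~imputed.any(axis=0)
        x = x[:, keep]
        imputed = imputed[:, keep]
    if x.shape[1] < 3:
        raise InsufficientDataError(f"PCA needs >= 3 cells, found {x.shape[1]}")

    observed = ~imputed
    if imputed.any():
        cov = _masked_covariance(x, observed)
    else:
        xc = x - x.mean(axis=1, keepdims=True)
        cov = (xc @ xc.T) / (x.shape[1] - 1)

    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # pairwise-complete covariance need not be PSD; variance shares come
    # from the nonnegative part of the spectrum
    pos = np.clip(eigval, 0.0, None)
    total = pos.sum()
    if total == 0:
        raise InsufficientDataError("expression is constant; PCA is undefined")
    shares = pos / total
    cum = np.cumsum(shares)
    n_sel = int(np.searchsorted(cum, variance_threshold, side="right") + 1)
    n_sel = min(n_sel, len(shares))
    scores = np.abs(eigvec[:, :n_sel]).sum(axis=1)
    return PcaScoreTable(
        genes=matrix.genes[gidx],
        scores=scores,
        n_components_selected=n_sel,
        cumulative_variance=float(cum[n_sel - 1]),
        variance_shares=shares,
    )


def rank_genes(table: PcaScoreTable) -> pd.DataFrame:
    """Rank genes by score, descending; ties broken by gene id (ascending)."""
    frame = pd.DataFrame({"gene": table.genes, "score": table.scores})
    frame = frame.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return frame.reset_index(drop=True)


def enrichment_score(
    ranked_genes: np.ndarray,
    ranked_scores: np.ndarray,
    members: set,
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, int]:
    """Weighted Kolmogorov-Smirnov enrichment score for one set.

    Walking down the ranked list, hits increment the running sum by
    |score|^p normalized over the set's hits, misses decrement it by
    1/(N - N_hit). ES is the running-sum value of largest magnitude.
    Returns (ES, running sum, index of the extreme deviation).
    """
    n = len(ranked_genes)
    hit = np.fromiter((g in members for g in ranked_genes), dtype=bool, count=n)
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ConfigError("gene set must overlap the list partially")
    w = np.where(hit, np.abs(ranked_scores) ** weight_exponent, 0.0)
    total_w = w.sum()
    if total_w == 0:  # all hit scores are 0: fall back to unweighted steps
        w = hit.astype(float)
        total_w = w.sum()
    step = w / total_w - (~hit) / (n - n_hit)
    running = np.cumsum(step)
    i_max = int(np.argmax(np.abs(running)))
    return float(running[i_max]), running, i_max


def gsea_preranked(
    ranked: pd.DataFrame,
    gene_sets: GeneSetCollection,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = 0,
    min_size: int = 1,
) -> GseaResult:
    """Preranked GSEA over the collection's metabolic sets.

    ``ranked`` is the output of :func:`rank_genes` (columns ``gene``,
    ``score``, best-first). Null distribution: gene-label permutations —
    random same-size subsets of the ranked list. NES is ES divided by
    the mean |ES*| of same-sign permutations; the p-value uses the
    add-one estimator among same-sign permutations. BH adjustment across
    sets is reported alongside the raw p.
    """
    if len(ranked) == 0:
        raise ConfigError("ranked gene list is empty")
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    gene_pos = set(genes)
    rng = np.random.default_rng(seed)

    rows = []
    absent = []
    for name, members in gene_sets.metabolic_sets.items():
        overlap = [g for g in members if g in gene_pos]
        if len(overlap) < min_size or len(overlap) >= len(genes):
            absent.append(name)
            continue
        mset = set(overlap)
        es, running, i_max = enrichment_score(genes, scores, mset, weight_exponent)
        if es >= 0:
            le = [g for g in genes[: i_max + 1] if g in mset]
        else:
            le = [g for g in genes[i_max:] if g in mset]

        size = len(mset)
        es_null = np.empty(n_perm)
        for b in range(n_perm):
            hit = np.zeros(len(genes), dtype=bool)
            hit[rng.choice(len(genes), size=size, replace=False)] = True
            w = np.where(hit, np.abs(scores) ** weight_exponent, 0.0)
            tw = w.sum()
            if tw == 0:
                w = hit.astype(float)
                tw = w.sum()
            step = w / tw - (~hit) / (len(genes) - size)
            run = np.cumsum(step)
            es_null[b] = run[np.argmax(np.abs(run))]

        same = es_null[es_null >= 0] if es >= 0 else es_null[es_null < 0]
        if len(same) == 0:
            p = 1.0 / (1.0 + n_perm)
            nes = np.nan
        else:
            p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + len(same))
            denom = np.mean(np.abs(same))
            nes = es / denom if denom > 0 else np.nan
        rows.append({
            "set": name, "size": size, "es": es, "nes": nes,
            "p_value": p, "leading_edge": ",".join(le),
        })

    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table = table.sort_values("nes", ascending=False, na_position="last").reset_index(drop=True)
    return GseaResult(table, absent, n_perm, weight_exponent, seed)
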