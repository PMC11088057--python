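"""Per-cell signature scores, hypoxia correlations, and group comparisons.

Pathway activity (the per-cell-type score) cannot place one dot per cell
on a scatter plot, so per-cell "activity" here is a signature score: the
mean over a gene set of per-gene z-scored (imputed, log2-scale)
expression. Hypoxia vs glycolysis / OXPHOS coupling is then the per-cell-
type correlation (Spearman by default — robust to the skewed score
distributions; Pearson available) between those scores.

Transporter-family comparisons between tissue groups report, per gene,
log2((mean TPM tumor + 1) / (mean TPM normal + 1)) with a two-sided
rank-sum p-value over cells, plus dot-plot summaries per cluster (mean
expression min-max scaled to [0, 1] across clusters; fraction of cells
expressing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CellAnnotation, ExpressionMatrix
from .errors import ConfigError, InsufficientDataError, ValidationError

MIN_CELLS_PER_TYPE_CORR = 10


def score_cells(matrix: ExpressionMatrix, genes: list[str] | tuple[str, ...]) -> pd.Series:
    """Signature score per cell: mean of per-gene z-scores over the set.

    Genes absent from the matrix are skipped (reported via the returned
    series' ``attrs["absent_genes"]``); genes constant across cells have
    no z-score and are skipped with a warning. If nothing remains the set
    cannot be scored and an error is raised.
    """
    idx = matrix.genes.get_indexer(pd.Index(genes))
    absent = [g for g, i in zip(genes, idx) if i < 0]
    idx = idx[idx >= 0]
    if len(idx) == 0:
        raise ValidationError("gene set has no overlap with the matrix")
    sub = matrix.values[idx, :]
    sd = sub.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} signature genes constant across cells were skipped",
            stacklevel=2,
        )
    if constant.all():
        raise ValidationError("all signature genes are constant across cells")
    keep = ~constant
    z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    series = pd.Series(z.mean(axis=0), index=matrix.cells)
    series.attrs["absent_genes"] = absent
    series.attrs["constant_genes"] = list(matrix.genes[idx][constant])
    return series


@dataclass
class CellSignatureScores:
    """Per-cell hypoxia / glycolysis / OXPHOS signature scores."""

    scores: pd.DataFrame  # cells x {"hypoxia", "glycolysis", "oxphos", ...}

    @classmethod
    def compute(
        cls,
        matrix: ExpressionMatrix,
        sets: dict[str, list[str] | tuple[str, ...]],
    ) -> "CellSignatureScores":
        cols = {name: score_cells(matrix, genes) for name, genes in sets.items()}
        return cls(pd.DataFrame(cols))


def correlate_by_type(
    scores: CellSignatureScores,
    annotation: CellAnnotation,
    reference: str = "hypoxia",
    method: str = "spearman",
) -> pd.DataFrame:
    """Per-cell-type correlation of each signature against the reference.

    Returns a long table (cell_type, pathway, r, p, n, method); types
    with fewer than 10 cells are reported absent (NaN r/p). Two-sided
    p-values.
    """
    if method not in ("spearman", "pearson"):
        raise ConfigError("method must be 'spearman' or 'pearson'")
    frame = scores.scores
    if reference not in frame.columns:
        raise ConfigError(f"reference signature {reference!r} not scored")
    ann = annotation.table.loc[frame.index]
    rows = []
    corr_fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    for ctype, sub in frame.groupby(ann["cell_type"], sort=True):
        for pathway in [c for c in frame.columns if c != reference]:
            n = len(sub)
            if n < MIN_CELLS_PER_TYPE_CORR:
                rows.append({"cell_type": ctype, "pathway": pathway,
                             "r": np.nan, "p": np.nan, "n": n, "method": method})
                continue
            res = corr_fn(sub[reference], sub[pathway])
            rows.append({"cell_type": ctype, "pathway": pathway,
                         "r": float(res.statistic), "p": float(res.pvalue),
                         "n": n, "method": method})
    return pd.DataFrame(rows)


@dataclass
class GeneGroupComparison:
    """Tumor-vs-normal comparison for a list of genes.

    ``summary``: per gene, log2 fold change and rank-sum p over cells.
    ``dotplot``: per gene x cluster, min-max-scaled mean expression and
    fraction of cells with expression > 0. ``absent``: requested genes
    not in the matrix.
    """

    summary: pd.DataFrame
    dotplot: pd.DataFrame
    absent: list[str]


def compare_groups(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    genes: list[str] | tuple[str, ...],
) -> GeneGroupComparison:
    """Compare per-gene expression between the tumor and normal groups.

    Expects TPM-stage values (fold changes are defined on the TPM scale:
    log2FC = log2((mean tumor + 1)/(mean normal + 1)), pseudocount 1
    matching the pipeline's log2(TPM+1) convention). The rank-sum test is
    two-sided over cells and is invariant to the log transform anyway.
    """
    ann = annotation.for_matrix(matrix)
    groups = set(ann["tissue_group"])
    if groups != {"tumor", "normal"}:
        raise InsufficientDataError(
            f"both tissue groups required, found {sorted(groups)}"
        )
    tumor = (ann["tissue_group"] == "tumor").to_numpy()
    normal = ~tumor

    idx = matrix.genes.get_indexer(pd.Index(genes))
    absent = [g for g, i in zip(genes, idx) if i < 0]
    present = [(g, i) for g, i in zip(genes, idx) if i >= 0]

    rows = []
    dot_rows = []
    ctypes = sorted(ann["cell_type"].unique())
    type_masks = {t: (ann["cell_type"] == t).to_numpy() for t in ctypes}
    for g, i in present:
        x = matrix.values[i, :]
        mt, mn = x[tumor].mean(), x[normal].mean()
        log2fc = float(np.log2((mt + 1.0) / (mn + 1.0)))
        mw = stats.mannwhitneyu(x[tumor], x[normal], alternative="two-sided")
        rows.append({"gene": g, "log2fc": log2fc, "p_value": float(mw.pvalue),
                     "mean_tumor": mt, "mean_normal": mn})

        means = np.array([x[type_masks[t]].mean() for t in ctypes])
        fracs = np.array([(x[type_masks[t]] > 0).mean() for t in ctypes])
        lo, hi = means.min(), means.max()
        scaled = (means - lo) / (hi - lo) if hi > lo else np.zeros_like(means)
        for t, m, f, s in zip(ctypes, means, fracs, scaled):
            dot_rows.append({"gene": g, "cluster": t, "mean_expression": m,
                             "scaled_mean": s, "fraction_expressing": f})
    return GeneGroupComparison(pd.DataFrame(rows), pd.DataFrame(dot_rows), absent)
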