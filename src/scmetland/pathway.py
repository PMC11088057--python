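"""Cell-type metabolic pathway activity with permutation significance.

For each metabolic gene g and cell type t the pipeline computes the mean
(imputed, log2-scale) expression E_{g,t} and the relative expression

    r_{g,t} = E_{g,t} / mean_t' E_{g,t'}

so r is centred at 1: a value of 1.3 means the gene sits 30% above its
across-type average in that type. A pathway's activity in a type is the
weighted average of its member genes' relative expression,

    PA_{p,t} = sum_{g in p} w_g r_{g,t} / sum_{g in p} w_g,

with weights w_g = 1/(number of metabolic pathways containing g) so that
genes shared between pathways are not double counted, and with per-
pathway-per-type Tukey-fence outliers excluded from the average.
Significance comes from a permutation null: cell-type labels are
shuffled across cells (preserving type sizes) and the two-sided
extremeness |PA - 1| is compared against the permuted distribution with
the add-one estimator, which can never return 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CellAnnotation, ExpressionMatrix, GeneSetCollection
from .errors import ConfigError, InsufficientDataError

DEFAULT_TUKEY_K = 1.5
DEFAULT_MIN_GENES = 5
DEFAULT_SEED = 1729


@dataclass
class RelativeExpressionTable:
    """Per-gene, per-cell-type mean and relative expression.

    ``retained`` marks genes with a nonzero mean in at least one type;
    genes that are zero everywhere have undefined relative expression and
    are excluded downstream (their ids are listed in ``excluded_genes``).
    ``outlier_flags`` holds, per pathway, a boolean (member gene x type)
    matrix filled in by :func:`flag_outliers`; flags only ever exclude a
    value from score aggregation, never delete it.
    """

    genes: pd.Index
    cell_types: list[str]
    mean_expression: np.ndarray      # (G, T)
    relative_expression: np.ndarray  # (G, T), NaN where undefined
    retained: np.ndarray             # (G,) bool
    outlier_flags: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def excluded_genes(self) -> list[str]:
        return list(self.genes[~self.retained])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.relative_expression, index=self.genes, columns=self.cell_types)


@dataclass
class PathwayActivityResult:
    """Pathway x cell-type activity scores with optional permutation p-values.

    ``scores`` is NaN where a pathway had fewer than ``min_genes`` usable
    genes in that type ("absent", not zero). ``displayed`` mirrors the
    heatmap convention of blanking non-significant values (p > 0.05).
    """

    pathways: list[str]
    cell_types: list[str]
    scores: np.ndarray              # (P, T)
    n_genes: np.ndarray             # (P, T) int, genes aggregated per entry
    p_values: np.ndarray | None = None  # (P, T), in (0, 1]
    n_perm: int = 0
    seed: int | None = None
    alpha: float = 0.05

    @property
    def displayed(self) -> np.ndarray:
        if self.p_values is None:
            return ~np.isnan(self.scores)
        return (~np.isnan(self.scores)) & (self.p_values <= self.alpha)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.pathways):
            for j, t in enumerate(self.cell_types):
                rows.append({
                    "pathway": p,
                    "cell_type": t,
                    "score": self.scores[i, j],
                    "p_value": None if self.p_values is None else self.p_values[i, j],
                    "n_genes": int(self.n_genes[i, j]),
                    "displayed": bool(self.displayed[i, j]),
                })
        return pd.DataFrame(rows)

    def to_wide_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.pathways, columns=self.cell_types)


def _type_means(values: np.ndarray, type_codes: np.ndarray, n_types: int) -> np.ndarray:
    """(genes x types) mean expression given integer type codes per cell."""
    onehot = np.zeros((values.shape[1], n_types))
    onehot[np.arange(values.shape[1]), type_codes] = 1.0
    counts = onehot.sum(axis=0)
    return (values @ onehot) / counts


def _relative(mean_expr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relative expression and the retained-gene mask."""
    grand = mean_expr.mean(axis=1, keepdims=True)
    retained = grand[:, 0] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(retained[:, None], mean_expr / grand, np.nan)
    return rel, retained


def relative_expression(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
) -> RelativeExpressionTable:
    """Mean and relative expression per gene per cell type.

    For each retained gene the relative values average to exactly 1
    across types. Requires at least two cell types.
    """
    ann = annotation.for_matrix(matrix)
    types = sorted(ann["cell_type"].unique())
    if len(types) < 2:
        raise InsufficientDataError(
            f"relative expression needs >= 2 cell types, found {len(types)}"
        )
    codes = pd.Categorical(ann["cell_type"], categories=types).codes
    mean_expr = _type_means(matrix.values, np.asarray(codes), len(types))
    rel, retained = _relative(mean_expr)
    return RelativeExpressionTable(matrix.genes, types, mean_expr, rel, retained)


def _tukey_flags(member_rel: np.ndarray, k: float) -> np.ndarray:
    """Tukey-fence outlier flags for one pathway's (members x types) r-block.

    A value is flagged iff it falls outside [Q1 - k*IQR, Q3 + k*IQR] of
    the pathway's member values in that cell type.
    """
    flags = np.zeros(member_rel.shape, dtype=bool)
    if not np.isfinite(k):
        return flags
    for j in range(member_rel.shape[1]):
        col = member_rel[:, j]
        ok = ~np.isnan(col)
        if ok.sum() < 4:  # quartile fences are meaningless below 4 points
            continue
        q1, q3 = np.percentile(col[ok], [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        flags[:, j] = ok & ((col < lo) | (col > hi))
    return flags


def flag_outliers(
    table: RelativeExpressionTable,
    gene_sets: GeneSetCollection,
    k: float = DEFAULT_TUKEY_K,
) -> RelativeExpressionTable:
    """Flag per-pathway relative-expression outliers (Tukey fences, k=1.5).

    Fences are computed within each pathway and cell type over the
    pathway's member genes, so a gene shared between pathways can be an
    outlier in one pathway and not another. As k -> inf no value is ever
    flagged.
    """
    table.outlier_flags = {}
    for name, members in gene_sets.metabolic_sets.items():
        idx = table.genes.get_indexer(pd.Index(members))
        idx = idx[idx >= 0]
        block = table.relative_expression[idx, :]
        table.outlier_flags[name] = _tukey_flags(block, k)
    return table


def pathway_activity_scores(
    table: RelativeExpressionTable,
    gene_sets: GeneSetCollection,
    min_genes: int = DEFAULT_MIN_GENES,
) -> PathwayActivityResult:
    """Weighted-average pathway activity from a relative-expression table.

    Uses the collection's 1/multiplicity weights; flagged outliers and
    non-retained genes are excluded from the average. Entries with fewer
    than ``min_genes`` usable genes are reported absent (NaN).
    """
    weights = gene_sets.weights
    names = list(gene_sets.metabolic_sets)
    T = len(table.cell_types)
    scores = np.full((len(names), T), np.nan)
    n_used = np.zeros((len(names), T), dtype=int)
    for i, name in enumerate(names):
        members = gene_sets[name]
        idx = table.genes.get_indexer(pd.Index(members))
        present = idx >= 0
        idx = idx[present]
        if len(idx) == 0:
            continue
        w = np.array([weights[m] for m, p in zip(members, present) if p])
        rel = table.relative_expression[idx, :]
        usable = table.retained[idx][:, None] & ~np.isnan(rel)
        flags = table.outlier_flags.get(name)
        if flags is not None:
            usable &= ~flags
        wmat = np.where(usable, w[:, None], 0.0)
        denom = wmat.sum(axis=0)
        numer = np.where(usable, rel, 0.0)
        numer = (numer * wmat).sum(axis=0)
        n_used[i, :] = usable.sum(axis=0)
        enough = n_used[i, :] >= min_genes
        with np.errstate(invalid="ignore", divide="ignore"):
            col = np.where(enough & (denom > 0), numer / denom, np.nan)
        scores[i, :] = col
    return PathwayActivityResult(names, list(table.cell_types), scores, n_used)


def _scores_for_labels(
    values: np.ndarray,
    type_codes: np.ndarray,
    n_types: int,
    set_indices: list[np.ndarray],
    set_weights: list[np.ndarray],
    tukey_k: float,
    min_genes: int,
) -> np.ndarray:
    """(pathways x types) activity for one labelling; shared by the
    observed computation and every permutation, so the null applies
    exactly the same aggregation (including outlier fences)."""
    mean_expr = _type_means(values, type_codes, n_types)
    rel, retained = _relative(mean_expr)
    P = len(set_indices)
    scores = np.full((P, n_types), np.nan)
    for i in range(P):
        idx = set_indices[i]
        if len(idx) == 0:
            continue
        block = rel[idx, :]
        usable = retained[idx][:, None] & ~np.isnan(block)
        usable &= ~_tukey_flags(block, tukey_k)
        wmat = np.where(usable, set_weights[i][:, None], 0.0)
        denom = wmat.sum(axis=0)
        numer = (np.where(usable, block, 0.0) * wmat).sum(axis=0)
        enough = usable.sum(axis=0) >= min_genes
        with np.errstate(invalid="ignore", divide="ignore"):
            scores[i, :] = np.where(enough & (denom > 0), numer / denom, np.nan)
    return scores


def permutation_test(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    gene_sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = DEFAULT_SEED,
    tukey_k: float = DEFAULT_TUKEY_K,
    min_genes: int = DEFAULT_MIN_GENES,
) -> PathwayActivityResult:
    """Pathway activity with label-permutation p-values.

    Each iteration shuffles the full cell-type label column across cells
    (type sizes preserved — the standard exchangeability null for
    cell-type programs) and recomputes every pathway activity score with
    the identical aggregation. The two-sided p-value for (p, t) is

        p = (1 + #{permutations with |PA* - 1| >= |PA_obs - 1|}) / (1 + n_perm),

    so it lies in (0, 1] by construction. Deterministic under a fixed seed.
    """
    if n_perm < 100:
        raise ConfigError(f"n_perm must be >= 100, got {n_perm}")
    ann = annotation.for_matrix(matrix)
    types = sorted(ann["cell_type"].unique())
    if len(types) < 2:
        raise InsufficientDataError("permutation test needs >= 2 cell types")
    codes = np.asarray(pd.Categorical(ann["cell_type"], categories=types).codes)

    weights = gene_sets.weights
    names = list(gene_sets.metabolic_sets)
    set_indices, set_weights = [], []
    for name in names:
        members = gene_sets[name]
        idx = matrix.genes.get_indexer(pd.Index(members))
        present = idx >= 0
        set_indices.append(idx[present])
        set_weights.append(np.array([weights[m] for m, p in zip(members, present) if p]))

    observed = _scores_for_labels(
        matrix.values, codes, len(types), set_indices, set_weights, tukey_k, min_genes
    )
    obs_dev = np.abs(observed - 1.0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(observed.shape)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        sc = _scores_for_labels(
            matrix.values, perm, len(types), set_indices, set_weights, tukey_k, min_genes
        )
        dev = np.abs(sc - 1.0)
        # a permuted score that is absent cannot exceed the observed one
        exceed += np.where(np.isnan(dev) | np.isnan(obs_dev), 0.0, dev >= obs_dev)

    p = (1.0 + exceed) / (1.0 + n_perm)
    p = np.where(np.isnan(observed), np.nan, p)
    n_used = np.zeros(observed.shape, dtype=int)
    base = pathway_activity_scores(
        flag_outliers(relative_expression(matrix, annotation), gene_sets, tukey_k),
        gene_sets, min_genes,
    )
    n_used[:, :] = base.n_genes
    return PathwayActivityResult(
        names, types, observed, n_used, p_values=p, n_perm=n_perm, seed=seed
    )
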