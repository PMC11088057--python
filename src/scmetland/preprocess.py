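"""Expression preprocessing: log2(TPM+1), rare-type filtering, imputation.

The scoring pipeline works on log2(TPM+1) values, drops cell types with
fewer than 50 cells, and fills technical zeros by imputation while
recording exactly which entries were filled — downstream PCA excludes
those entries, so the mask is load-bearing, not cosmetic.

The protocol the pipeline follows does not pin down one imputation
algorithm, so two are provided behind a single interface: ``knn_smooth``
(fill a cell's zeros with the mean of its k most correlated neighbours
within the same tissue group and cell type) and ``low_rank`` (truncated
SVD reconstruction of the zero entries). ``none`` is the identity. All
methods obey the same contract: only zero entries may change, changed
entries are flagged, values stay nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CellAnnotation, ExpressionMatrix
from .errors import ConfigError, InsufficientDataError, StateError

IMPUTATION_METHODS = ("none", "knn_smooth", "low_rank")


@dataclass
class PreprocessConfig:
    min_cells_per_type: int = 50
    log_transform: bool = True
    imputation: str = "knn_smooth"
    k_neighbors: int = 10
    rank: int = 10
    within_tissue_group: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_cells_per_type < 1:
            raise ConfigError("min_cells_per_type must be >= 1")
        if self.imputation not in IMPUTATION_METHODS:
            raise ConfigError(f"imputation must be one of {IMPUTATION_METHODS}")
        if self.k_neighbors < 1:
            raise ConfigError("k_neighbors must be >= 1")
        if self.rank < 1:
            raise ConfigError("rank must be >= 1")


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """v -> log2(v + 1), stage tpm -> log2tpm1. Mask is untouched."""
    if matrix.stage != "tpm":
        raise StateError(f"log_transform expects stage 'tpm', got {matrix.stage!r}")
    return ExpressionMatrix(
        np.log2(matrix.values + 1.0), matrix.genes, matrix.cells,
        stage="log2tpm1", imputed=matrix.imputed.copy(),
    )


def filter_cell_types(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    min_cells: int = 50,
) -> tuple[ExpressionMatrix, CellAnnotation, dict]:
    """Drop cell types represented by fewer than ``min_cells`` cells.

    A type with exactly ``min_cells`` cells is retained ("fewer than"
    is strict). Returns the filtered matrix and annotation plus a report
    of kept/dropped types with their cell counts. Idempotent.
    """
    ann = annotation.for_matrix(matrix)
    counts = ann["cell_type"].value_counts().to_dict()
    dropped = {t: c for t, c in counts.items() if c < min_cells}
    kept = {t: c for t, c in counts.items() if c >= min_cells}
    if not kept:
        raise InsufficientDataError(
            f"all {len(counts)} cell types have fewer than {min_cells} cells"
        )
    keep_mask = (~ann["cell_type"].isin(dropped)).to_numpy()
    out = matrix.subset_cells(keep_mask)
    report = {
        "min_cells": min_cells,
        "kept": dict(sorted(kept.items())),
        "dropped": dict(sorted(dropped.items())),
        "n_cells_before": matrix.n_cells,
        "n_cells_after": out.n_cells,
    }
    return out, annotation.subset(out.cells), report


def impute(
    matrix: ExpressionMatrix,
    config: PreprocessConfig | None = None,
    annotation: CellAnnotation | None = None,
) -> ExpressionMatrix:
    """Fill technical zeros; every changed entry is flagged in the mask.

    Operates on log2(TPM+1) values. ``knn_smooth`` needs an annotation to
    define neighbourhoods (same tissue group and cell type); without one,
    all cells form a single pool. Observed nonzero entries are never
    modified, so genuine biological signal cannot be overwritten.
    """
    config = config or PreprocessConfig()
    if matrix.stage != "log2tpm1":
        raise StateError(f"impute expects stage 'log2tpm1', got {matrix.stage!r}")

    if config.imputation == "none":
        out = matrix.copy()
        out.stage = "imputed"
        return out

    values = matrix.values
    zeros = values == 0.0
    if not zeros.any():
        out = matrix.copy()
        out.stage = "imputed"
        return out

    filled = values.copy()
    if config.imputation == "knn_smooth":
        for cols in _cell_groups(matrix, annotation, config.within_tissue_group):
            _knn_fill(filled, values, zeros, cols, config.k_neighbors)
    elif config.imputation == "low_rank":
        for cols in _cell_groups(matrix, annotation, config.within_tissue_group, by_type=False):
            _low_rank_fill(filled, values, zeros, cols, config.rank, config.seed)

    filled = np.maximum(filled, 0.0)
    changed = filled != values
    assert not (changed & ~zeros).any(), "imputation touched an observed nonzero entry"
    return ExpressionMatrix(filled, matrix.genes, matrix.cells, stage="imputed", imputed=changed)


def _cell_groups(matrix, annotation, within_tissue, by_type=True):
    """Column-index groups over which imputation pools information."""
    if annotation is None:
        yield np.arange(matrix.n_cells)
        return
    ann = annotation.for_matrix(matrix)
    keys = []
    if within_tissue:
        keys.append("tissue_group")
    if by_type:
        keys.append("cell_type")
    if not keys:
        yield np.arange(matrix.n_cells)
        return
    for _, sub in ann.groupby(keys, sort=True):
        yield matrix.cells.get_indexer(sub.index)


def _knn_fill(filled, values, zeros, cols, k):
    """Fill zeros of each cell with the mean of its k nearest cells
    (Pearson correlation distance) in the same group."""
    sub = values[:, cols]
    n = sub.shape[1]
    if n < 2:
        return
    k_eff = min(k, n - 1)
    centred = sub - sub.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centred, axis=0)
    norms[norms == 0] = 1.0
    corr = (centred.T @ centred) / np.outer(norms, norms)
    np.fill_diagonal(corr, -np.inf)  # a cell is not its own neighbour
    nbr = np.argpartition(-corr, k_eff - 1, axis=1)[:, :k_eff]
    for j in range(n):
        col = cols[j]
        zg = zeros[:, col]
        if not zg.any():
            continue
        filled[zg, col] = sub[np.ix_(zg, nbr[j])].mean(axis=1)


def _low_rank_fill(filled, values, zeros, cols, rank, seed, n_iter=20, tol=1e-6):
    """Fill zeros from an iterated truncated-SVD reconstruction.

    Hard-impute scheme: zeros start at the gene means of the observed
    entries, then the block is repeatedly projected to rank ``rank`` and
    only the zero entries are refreshed, until the refill converges. A
    single SVD on the zero-corrupted block would be biased toward zero.
    """
    from sklearn.utils.extmath import randomized_svd

    sub = values[:, cols]
    r = min(rank, min(sub.shape) - 1)
    if r < 1:
        return
    zg = zeros[:, cols]
    obs = ~zg
    counts = np.maximum(obs.sum(axis=1, keepdims=True), 1)
    gene_means = (sub * obs).sum(axis=1, keepdims=True) / counts
    work = np.where(zg, np.broadcast_to(gene_means, sub.shape), sub)
    for _ in range(n_iter):
        u, s, vt = randomized_svd(work, n_components=r, random_state=seed)
        recon = (u * s) @ vt
        new = np.where(zg, np.maximum(recon, 0.0), sub)
        delta = np.abs(new[zg] - work[zg]).max() if zg.any() else 0.0
        work = new
        if delta < tol:
            break
    block = filled[:, cols]
    block[zg] = work[zg]
    filled[:, cols] = block
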