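"""In-memory containers shared across the pipeline.

The pipeline moves four kinds of data around: a gene x cell expression
matrix (TPM or log2(TPM+1), with a per-entry "was imputed" mask), a
per-cell annotation table, a collection of named gene sets with derived
pathway-multiplicity weights, and a clinical immunohistochemistry cohort.
They are thin typed wrappers over numpy/pandas objects so that every stage
can validate its preconditions cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Allowed values of :attr:`ExpressionMatrix.stage`.
STAGES = ("tpm", "log2tpm1", "imputed")

#: TPM vectors sum to this per cell by construction.
TPM_SCALE = 1.0e6


@dataclass
class ExpressionMatrix:
    """Dense gene x cell expression matrix with stage and imputation mask.

    Parameters
    ----------
    values
        ``(n_genes, n_cells)`` float array. Nonnegative at every stage.
    genes, cells
        Unique string identifiers for rows and columns.
    stage
        ``"tpm"`` raw TPM, ``"log2tpm1"`` after log transform,
        ``"imputed"`` after zero-filling. The mask is all-``False``
        until the imputation stage.
    imputed
        Boolean array of the same shape; ``True`` marks entries whose
        value was filled in by imputation rather than observed.
    """

    values: np.ndarray
    genes: pd.Index
    cells: pd.Index
    stage: str = "tpm"
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = pd.Index(self.genes, dtype=object)
        self.cells = pd.Index(self.cells, dtype=object)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D gene x cell array")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.genes.has_duplicates:
            dup = self.genes[self.genes.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if self.cells.has_duplicates:
            dup = self.cells[self.cells.duplicated()][0]
            raise ValidationError(f"duplicate cell id {dup!r}")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be nonnegative")
        if self.imputed is None:
            self.imputed = np.zeros(self.values.shape, dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)
            if self.imputed.shape != self.values.shape:
                raise ValidationError("imputed mask shape differs from values shape")
        if self.stage != "imputed" and self.imputed.any():
            raise ValidationError("imputed mask must be all-False before the imputation stage")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.genes.copy(), self.cells.copy(),
            stage=self.stage, imputed=self.imputed.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Return a genes x cells DataFrame view (copy) of the values."""
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)

    def gene_indexer(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of the given genes; absent genes are dropped."""
        idx = self.genes.get_indexer(pd.Index(genes))
        return idx[idx >= 0]

    def subset_cells(self, cell_mask: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[:, cell_mask], self.genes, self.cells[cell_mask],
            stage=self.stage, imputed=self.imputed[:, cell_mask],
        )


@dataclass
class CellAnnotation:
    """Per-cell sample / tissue-group / cell-type labels.

    ``table`` is indexed by cell id and carries columns ``sample_id``,
    ``tissue_group`` (``"tumor"`` or ``"normal"``) and ``cell_type``.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "tissue_group", "cell_type")
    TISSUE_GROUPS = ("tumor", "normal")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns {missing}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"cell {dup!r} annotated more than once")
        bad = set(self.table["tissue_group"]) - set(self.TISSUE_GROUPS)
        if bad:
            raise ValidationError(
                f"tissue_group values {sorted(bad)} not in {self.TISSUE_GROUPS}"
            )

    def for_matrix(self, matrix: ExpressionMatrix) -> pd.DataFrame:
        """Annotation rows aligned to the matrix's cell order.

        Cells present in the matrix but absent from the annotation are an
        error: dropping them silently would corrupt per-type means.
        """
        missing = matrix.cells.difference(self.table.index)
        if len(missing) > 0:
            raise ValidationError(
                f"{len(missing)} matrix cells lack annotation, e.g. {missing[0]!r}"
            )
        return self.table.loc[matrix.cells]

    def subset(self, cells: pd.Index) -> "CellAnnotation":
        return CellAnnotation(self.table.loc[cells].copy())

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())


class GeneSetCollection:
    """Named gene sets plus derived per-gene multiplicity weights.

    Metabolic pathway sets participate in the weighting scheme: a gene
    appearing in ``k`` metabolic sets gets weight ``w_g = 1/k``, so genes
    shared between pathways are not double counted when pathway activity
    scores are averaged. Signature sets (e.g. the hallmark hypoxia set)
    are carried alongside but excluded from the multiplicity counts.
    """

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]],
        signature_sets: Iterable[str] = (),
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self.sets: dict[str, tuple[str, ...]] = {}
        for name, members in sets.items():
            deduped = tuple(dict.fromkeys(members))  # de-duplicate, keep order
            if not deduped:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = deduped
        self.signature_sets = frozenset(signature_sets)
        unknown = self.signature_sets - set(self.sets)
        if unknown:
            raise ValidationError(f"signature sets {sorted(unknown)} not in collection")
        self.descriptions = dict(descriptions or {})
        self._weights: dict[str, float] | None = None

    @property
    def metabolic_sets(self) -> dict[str, tuple[str, ...]]:
        return {n: g for n, g in self.sets.items() if n not in self.signature_sets}

    @property
    def weights(self) -> dict[str, float]:
        """``w_g = 1 / (number of metabolic sets containing g)``."""
        if self._weights is None:
            counts: dict[str, int] = {}
            for members in self.metabolic_sets.values():
                for g in members:
                    counts[g] = counts.get(g, 0) + 1
            self._weights = {g: 1.0 / k for g, k in counts.items()}
        return self._weights

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


# IRS component ranges: staining intensity 0-3, percent-positive grade 1-3.
INTENSITY_RANGE = (0, 1, 2, 3)
PROPORTION_RANGE = (1, 2, 3)
IRS_HIGH_CUTOFF = 4


def derive_irs(intensity: int, proportion_grade: int) -> int:
    """Immunoreactivity score: intensity x percent-positive grade.

    Attainable values are the products of {0..3} x {1..3}: 0,1,2,3,4,6,9.
    """
    if intensity not in INTENSITY_RANGE:
        raise ValidationError(f"staining intensity {intensity} not in 0..3")
    if proportion_grade not in PROPORTION_RANGE:
        raise ValidationError(f"proportion grade {proportion_grade} not in 1..3")
    return intensity * proportion_grade


@dataclass
class IhcCohort:
    """Clinical IHC cohort: per-patient IRS components and binary features.

    ``table`` is indexed by patient id with columns ``intensity``,
    ``proportion_grade``, derived ``irs`` and ``expression_class``
    (``"high"`` iff IRS >= 4), plus one yes/no column per clinical feature.
    """

    table: pd.DataFrame
    feature_columns: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for col in ("intensity", "proportion_grade"):
            if col not in self.table.columns:
                raise ValidationError(f"cohort missing column {col!r}")
        irs = []
        for pid, row in self.table.iterrows():
            try:
                irs.append(derive_irs(int(row["intensity"]), int(row["proportion_grade"])))
            except ValidationError as err:
                raise ValidationError(f"patient {pid!r}: {err}") from None
        self.table = self.table.copy()
        self.table["irs"] = irs
        self.table["expression_class"] = np.where(
            self.table["irs"] >= IRS_HIGH_CUTOFF, "high", "low"
        )
        for col in self.feature_columns:
            if col not in self.table.columns:
                raise ValidationError(f"cohort missing feature column {col!r}")
            bad = set(self.table[col].unique()) - {"yes", "no"}
            if bad:
                raise ValidationError(f"feature {col!r} has non-binary values {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_high(self) -> int:
        return int((self.table["expression_class"] == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.table["expression_class"] == "low").sum())
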