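"""Readers and writers for the formats the pipeline touches.

Expression matrices travel as dense TSV (genes x cells, header row of
cell ids) or MatrixMarket coordinate triplets (1-based on disk, 0-based
in memory) with ``genes.tsv`` / ``barcodes.tsv`` sidecars; annotations
and clinical cohorts as CSV; gene sets as GMT (tab-separated: name,
description, members...).

Gene and cell id matching is case-sensitive exact string match — the
synthetic ids are controlled. ``read_gmt`` accepts ``case_fold=True``
for real MSigDB/KEGG files whose conventions vary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CellAnnotation, ExpressionMatrix, GeneSetCollection, IhcCohort
from .errors import FormatError, ValidationError

_SIDECAR_GENES = "genes.tsv"
_SIDECAR_CELLS = "barcodes.tsv"


def read_expression(path: str | Path, format: str = "tsv", stage: str = "tpm") -> ExpressionMatrix:
    """Read an expression matrix from TSV or MTX.

    For ``format="mtx"``, ``path`` is the ``.mtx`` file and the gene/cell
    id sidecars (``genes.tsv``, ``barcodes.tsv``) must sit next to it.
    Implicit zeros of the sparse form become explicit zeros.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path, stage)
    if format == "mtx":
        return _read_mtx(path, stage)
    raise ValidationError(f"unknown expression format {format!r}; expected 'tsv' or 'mtx'")


def _read_tsv(path: Path, stage: str) -> ExpressionMatrix:
    try:
        # round_trip parsing keeps shortest-repr floats bit-exact
        frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as err:  # pandas raises several parse error types
        raise FormatError(f"{path}: could not parse TSV ({err})") from err
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate cell id {dup!r}")
    values = frame.to_numpy(dtype=float)
    neg = np.argwhere(values < 0)
    if len(neg):
        g, _ = neg[0]
        raise FormatError(f"{path}: negative value at line {g + 2} (gene {frame.index[g]!r})")
    return ExpressionMatrix(values, frame.index.astype(str), frame.columns.astype(str), stage=stage)


def _read_mtx(path: Path, stage: str) -> ExpressionMatrix:
    genes_path = path.parent / _SIDECAR_GENES
    cells_path = path.parent / _SIDECAR_CELLS
    for p in (path, genes_path, cells_path):
        if not p.exists():
            raise FormatError(f"missing file {p}")
    try:
        mat = scipy.io.mmread(path)
    except Exception as err:
        raise FormatError(f"{path}: could not parse MatrixMarket ({err})") from err
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    genes = pd.Index([ln.split("\t")[0] for ln in genes_path.read_text().splitlines() if ln])
    cells = pd.Index([ln.split("\t")[0] for ln in cells_path.read_text().splitlines() if ln])
    if dense.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{path}: matrix is {dense.shape} but sidecars list "
            f"{len(genes)} genes x {len(cells)} cells"
        )
    if (dense < 0).any():
        raise FormatError(f"{path}: negative values in matrix")
    return ExpressionMatrix(dense, genes, cells, stage=stage)


def write_expression(matrix: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a matrix as TSV (bit-exact round trip via repr floats) or MTX
    (value-exact round trip; sidecars written next to the .mtx file)."""
    path = Path(path)
    if format == "tsv":
        frame = matrix.to_frame()
        # float_format=repr keeps the shortest exact decimal representation
        frame.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))
    elif format == "mtx":
        path.parent.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(matrix.values)
        scipy.io.mmwrite(path, sparse, precision=17)
        (path.parent / _SIDECAR_GENES).write_text("".join(f"{g}\n" for g in matrix.genes))
        (path.parent / _SIDECAR_CELLS).write_text("".join(f"{c}\n" for c in matrix.cells))
    else:
        raise ValidationError(f"unknown expression format {format!r}")


def read_annotation(path: str | Path) -> CellAnnotation:
    """Read a per-cell annotation CSV (cell_id, sample_id, tissue_group, cell_type)."""
    frame = pd.read_csv(path, index_col=0, dtype=str)
    return CellAnnotation(frame)


def write_annotation(annotation: CellAnnotation, path: str | Path) -> None:
    annotation.table.rename_axis("cell_id").to_csv(path)


def read_gmt(
    path: str | Path,
    signature_sets: tuple[str, ...] = (),
    signature_prefixes: tuple[str, ...] = ("HALLMARK_",),
    case_fold: bool = False,
) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Sets whose name is listed in ``signature_sets`` or starts with one of
    ``signature_prefixes`` (the hallmark hypoxia signature, by default)
    are carried as signatures and excluded from the pathway-multiplicity
    weight counts, which run over metabolic sets only.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
        name, desc, *members = fields
        members = [m for m in members if m]
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
        if case_fold:
            members = [m.upper() for m in members]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
        sets[name] = members
        descriptions[name] = desc
    signatures = {n for n in sets if n in signature_sets or n.startswith(signature_prefixes)}
    return GeneSetCollection(sets, signature_sets=signatures, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = collection.descriptions.get(name, "na")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("".join(f"{ln}\n" for ln in lines))


_CLINICAL_REQUIRED = ("intensity", "proportion_grade")


def read_clinical(path: str | Path, feature_columns: tuple[str, ...] | None = None) -> IhcCohort:
    """Read the clinical IHC CSV; derives IRS and high/low class on load.

    Columns other than patient id, intensity and proportion_grade are
    treated as binary clinical features unless ``feature_columns`` names
    them explicitly. Out-of-range staining components are rejected with
    the offending patient named.
    """
    frame = pd.read_csv(path, index_col=0)
    missing = [c for c in _CLINICAL_REQUIRED if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if feature_columns is None:
        derived = ("irs", "expression_class")
        feature_columns = tuple(
            c for c in frame.columns if c not in _CLINICAL_REQUIRED + derived
        )
    return IhcCohort(frame, feature_columns=feature_columns)


def write_clinical(cohort: IhcCohort, path: str | Path) -> None:
    cohort.table.rename_axis("patient_id").to_csv(path)
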