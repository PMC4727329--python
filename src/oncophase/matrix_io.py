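"""Typed matrix containers and readers/writers for the pipeline's file formats.

Matrices are stored samples-in-rows, genes-in-columns, mirroring the usual
cohort layout (m samples x n mutation genes, m x r expression genes). On-disk
format is plain TSV with a header row of gene labels and a first column of
sample labels. Somatic variants are consumed from MAF-like tab-separated
tables (minimum columns Hugo_Symbol, Tumor_Sample_Barcode,
Variant_Classification, optionally Protein_Change / HGVSp_Short).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DomainError,
    LabelError,
    MatrixParseError,
    SchemaError,
)

__all__ = [
    "MutationMatrix",
    "ExpressionMatrix",
    "BinaryExpressionMatrix",
    "VariantClass",
    "VariantRecord",
    "DEFAULT_CLASS_MAP",
    "read_matrix",
    "write_matrix",
    "read_maf",
    "write_solution",
]


def _check_labels(labels: Sequence[str], axis: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(labels) == 0:
        raise LabelError(f"empty {axis} label set")
    if len(set(labels)) != len(labels):
        dups = sorted({x for x in labels if list(labels).count(x) > 1})
        raise LabelError(f"duplicate {axis} labels: {dups[:5]}")
    return labels


@dataclass
class _LabelledMatrix:
    """Common machinery: label bookkeeping and pandas round-tripping."""

    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_labels(self.sample_ids, "sample")
        self.gene_ids = _check_labels(self.gene_ids, "gene")
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise DomainError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        self._validate_values()

    def _validate_values(self) -> None:  # overridden by subclasses
        raise NotImplementedError

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.gene_ids)
        )


def _validate_binary(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        bad = np.argwhere(~np.isin(arr, (0, 1)))
        i, j = bad[0]
        raise DomainError(
            f"{what} must contain only 0/1 entries; found {arr[i, j]!r} "
            f"at row {i}, column {j}"
        )
    return arr.astype(np.int8)


@dataclass
class MutationMatrix(_LabelledMatrix):
    """Binary m x n matrix; entry 1 means gene j carries a somatic mutation in sample i."""

    def _validate_values(self) -> None:
        self.values = _validate_binary(self.values, "mutation matrix")


@dataclass
class ExpressionMatrix(_LabelledMatrix):
    """Real-valued m x r matrix of log-normalized expression levels."""

    def _validate_values(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))
            i, j = bad[0]
            raise DomainError(
                f"expression matrix contains a non-finite value at row {i}, column {j}"
            )


@dataclass
class BinaryExpressionMatrix(_LabelledMatrix):
    """Binary m x r matrix; entry 1 flags outlier (extreme-percentile) expression."""

    def _validate_values(self) -> None:
        self.values = _validate_binary(self.values, "binary expression matrix")


class VariantClass(str, Enum):
    """Closed vocabulary of somatic variant consequences used by the driver screen."""

    MISSENSE = "missense"
    IN_FRAME_INDEL = "in_frame_indel"
    NONSENSE = "nonsense"
    NONSTOP = "nonstop"
    FRAMESHIFT_INDEL = "frameshift_indel"
    SILENT = "silent"
    OTHER = "other"


#: Default mapping from standard MAF Variant_Classification strings. Anything
#: not listed here (Splice_Site, Translation_Start_Site, UTR classes, ...)
#: falls back to OTHER: it counts toward a gene's variant total but toward
#: neither functional score.
DEFAULT_CLASS_MAP: dict[str, VariantClass] = {
    "Missense_Mutation": VariantClass.MISSENSE,
    "In_Frame_Ins": VariantClass.IN_FRAME_INDEL,
    "In_Frame_Del": VariantClass.IN_FRAME_INDEL,
    "Nonsense_Mutation": VariantClass.NONSENSE,
    "Nonstop_Mutation": VariantClass.NONSTOP,
    "Frame_Shift_Ins": VariantClass.FRAMESHIFT_INDEL,
    "Frame_Shift_Del": VariantClass.FRAMESHIFT_INDEL,
    "Silent": VariantClass.SILENT,
}


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant call.

    ``protein_position`` is the amino-acid residue index parsed from the
    protein-change notation (the first maximal digit run in e.g. "p.H1047R"),
    or None when unavailable.
    """

    gene: str
    sample: str
    variant_class: VariantClass
    protein_position: int | None = None

    def __post_init__(self) -> None:
        if self.protein_position is not None and self.protein_position < 1:
            raise DomainError(
                f"protein_position must be >= 1, got {self.protein_position}"
            )


_MATRIX_KINDS = {
    "mutation": MutationMatrix,
    "expression": ExpressionMatrix,
    "binary_expression": BinaryExpressionMatrix,
}


def read_matrix(
    path: str | Path,
    kind: str,
    transpose: bool = False,
):
    """Read a TSV matrix (header row = gene labels, first column = sample labels).

    Parameters
    ----------
    kind
        One of ``mutation``, ``expression``, ``binary_expression``; selects the
        returned container and its value domain.
    transpose
        Set when the file is genes-in-rows (the layout of TCGA expression
        files); the returned matrix is always samples x genes.
    """
    if kind not in _MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}; expected one of {sorted(_MATRIX_KINDS)}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        df = df.T
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise LabelError(f"{path}: duplicate row or column labels")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().values.any():
        i, j = np.argwhere(numeric.isna().values)[0]
        raise MatrixParseError(
            f"{path}: non-numeric cell {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    cls = _MATRIX_KINDS[kind]
    values = numeric.values
    if cls is not ExpressionMatrix:
        exact = values == np.round(values)
        ok = exact & np.isin(np.round(values), (0, 1))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise DomainError(
                f"{path}: {kind} matrix requires 0/1 cells; found {df.iat[i, j]!r} "
                f"at row {df.index[i]!r}, column {df.columns[j]!r}"
            )
        values = values.astype(np.int8)
    return cls(tuple(df.index), tuple(df.columns), values)


def write_matrix(matrix: _LabelledMatrix, path: str | Path) -> None:
    """Write a typed matrix back to TSV (inverse of :func:`read_matrix`)."""
    matrix.to_frame().to_csv(Path(path), sep="\t")


def _parse_protein_position(token: object) -> int | None:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    m = re.search(r"\d+", str(token))
    if m is None:
        return None
    pos = int(m.group(0))
    return pos if pos >= 1 else None


_REQUIRED_MAF_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")
_PROTEIN_COLUMNS = ("Protein_Change", "HGVSp_Short")


def read_maf(
    path: str | Path,
    class_map: Mapping[str, VariantClass] | None = None,
) -> list[VariantRecord]:
    """Read a MAF-like variant table into :class:`VariantRecord` objects.

    Unknown Variant_Classification strings map to :attr:`VariantClass.OTHER`.
    One record is produced per data row.
    """
    if class_map is None:
        class_map = DEFAULT_CLASS_MAP
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _REQUIRED_MAF_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required MAF column(s) {missing}")
    protein_col = next((c for c in _PROTEIN_COLUMNS if c in df.columns), None)
    records = []
    for row in df.itertuples(index=False):
        raw_class = getattr(row, "Variant_Classification")
        vclass = class_map.get(raw_class, VariantClass.OTHER)
        pos = (
            _parse_protein_position(getattr(row, protein_col))
            if protein_col is not None
            else None
        )
        records.append(
            VariantRecord(
                gene=getattr(row, "Hugo_Symbol"),
                sample=getattr(row, "Tumor_Sample_Barcode"),
                variant_class=vclass,
                protein_position=pos,
            )
        )
    return records


def write_solution(solution, path: str | Path) -> None:
    """Serialize a solved progression model to structured JSON text.

    Accepts any object exposing ``to_dict()`` (a ProgressionSolution) or a
    plain mapping.
    """
    payload = solution.to_dict() if hasattr(solution, "to_dict") else dict(solution)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
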