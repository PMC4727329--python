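"""Expression binarization and the mutation-expression connectivity matrix.

Connectivity C = E_bin^T . M counts, for each (expression gene h, mutation
gene j) pair, the samples in which h shows outlier expression while j is
mutated. Row-normalizing C turns each row into the distribution of gene h's
co-occurrence mass over mutation genes, which is how it enters the
progression model's expression-assignment constraint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DegenerateInputError, DomainError
from .matrix_io import (
    BinaryExpressionMatrix,
    ExpressionMatrix,
    MutationMatrix,
    _check_labels,
)

__all__ = [
    "ConnectivityMatrix",
    "binarize_expression",
    "connectivity",
    "normalize_rows",
    "read_connectivity",
    "write_connectivity",
]


@dataclass
class ConnectivityMatrix:
    """Nonnegative r x n matrix linking expression genes (rows) to mutation genes."""

    expr_gene_ids: tuple[str, ...]
    mut_gene_ids: tuple[str, ...]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.expr_gene_ids = _check_labels(self.expr_gene_ids, "expression gene")
        self.mut_gene_ids = _check_labels(self.mut_gene_ids, "mutation gene")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.expr_gene_ids), len(self.mut_gene_ids)):
            raise DomainError(
                f"connectivity shape {self.values.shape} does not match labels"
            )
        if (self.values < 0).any():
            raise DomainError("connectivity entries must be nonnegative")
        if self.normalized:
            sums = self.values.sum(axis=1)
            ok = np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12)
            if not ok.all():
                raise DomainError(
                    "normalized connectivity rows must sum to 1 (or 0 for "
                    "zero-connectivity genes)"
                )

    @property
    def n_expr_genes(self) -> int:
        return len(self.expr_gene_ids)

    @property
    def n_mut_genes(self) -> int:
        return len(self.mut_gene_ids)

    def zero_rows(self) -> np.ndarray:
        """Boolean mask of expression genes with no connectivity at all."""
        return self.values.sum(axis=1) == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=list(self.expr_gene_ids),
            columns=list(self.mut_gene_ids),
        )


def binarize_expression(
    E: ExpressionMatrix,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
) -> BinaryExpressionMatrix:
    """Flag extreme-percentile expression values per gene.

    For each gene column the lower/upper percentiles (linear interpolation
    between order statistics) are computed; entries at or beyond either
    threshold are set to 1. A gene with zero spread (lower percentile equal to
    the upper) yields an all-zero column: a constant gene has no outliers.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise DomainError(
            f"percentile bounds must satisfy 0 <= lower < upper <= 100, "
            f"got ({lower_pct}, {upper_pct})"
        )
    if E.n_samples < 2:
        raise DegenerateInputError(
            "binarization needs at least 2 samples per gene"
        )
    q_lo, q_hi = np.percentile(E.values, [lower_pct, upper_pct], axis=0)
    flagged = (E.values <= q_lo) | (E.values >= q_hi)
    flagged[:, q_lo == q_hi] = False
    return BinaryExpressionMatrix(
        E.sample_ids, E.gene_ids, flagged.astype(np.int8)
    )


def connectivity(Ebin: BinaryExpressionMatrix, M: MutationMatrix) -> ConnectivityMatrix:
    """Build the unnormalized co-occurrence matrix C = E_bin^T . M.

    Requires identical sample labels in identical order in both matrices.
    """
    if Ebin.sample_ids != M.sample_ids:
        raise AlignmentError(
            "expression and mutation matrices must share sample labels in the "
            "same order"
        )
    values = Ebin.values.astype(np.int64).T @ M.values.astype(np.int64)
    return ConnectivityMatrix(
        Ebin.gene_ids, M.gene_ids, values.astype(float), normalized=False
    )


def normalize_rows(C: ConnectivityMatrix) -> ConnectivityMatrix:
    """Scale each row to sum to 1; all-zero rows are left as zero.

    Zero rows correspond to expression genes with no mutation co-occurrence;
    downstream they end up assigned to no phase.
    """
    sums = C.values.sum(axis=1, keepdims=True)
    values = np.divide(C.values, sums, out=np.zeros_like(C.values), where=sums > 0)
    return ConnectivityMatrix(C.expr_gene_ids, C.mut_gene_ids, values, normalized=True)


def write_connectivity(C: ConnectivityMatrix, path: str | Path) -> None:
    C.to_frame().to_csv(Path(path), sep="\t")


def read_connectivity(path: str | Path, normalized: bool | None = None) -> ConnectivityMatrix:
    """Read a connectivity TSV; when ``normalized`` is None it is auto-detected
    from the row sums (every row summing to 1 or 0 within 1e-9)."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    values = df.values.astype(float)
    if normalized is None:
        sums = values.sum(axis=1)
        normalized = bool(
            np.all(np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12))
        )
    return ConnectivityMatrix(tuple(df.index), tuple(df.columns), values, normalized=normalized)
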