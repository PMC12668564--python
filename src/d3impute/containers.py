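"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`ExpressionMatrix`, a dense cell×gene
(or bulk-sample×gene) non-negative matrix with row/column identifiers
and optional per-cell annotations.  Single-cell matrices flow through
QC → transformation → discrimination → imputation without changing
container type; only the values and the retained rows/columns change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["ExpressionMatrix"]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class ExpressionMatrix:
    """A dense non-negative expression matrix with identifiers.

    Parameters
    ----------
    values
        ``(n_rows, n_genes)`` array; rows are cells (or bulk samples),
        columns are genes.  Absent measurements are stored as 0.
    cell_ids, gene_ids
        Unique row / column identifiers.
    labels
        Optional per-row categorical annotation (e.g. cell type).
    mito_pct
        Optional per-row mitochondrial percentage in ``[0, 100]``.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray | None = None
    mito_pct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite (store absent entries as 0)")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        n, m = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} columns")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels must be one entry per row")
        if self.mito_pct is not None:
            self.mito_pct = np.asarray(self.mito_pct, dtype=float)
            if self.mito_pct.shape != (n,):
                raise ValueError("mito_pct must be one entry per row")
            if np.any((self.mito_pct < 0) | (self.mito_pct > 100)):
                raise ValueError("mito_pct must lie in [0, 100]")

    # -- shape helpers -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- subsetting ----------------------------------------------------
    def subset_cells(self, idx: np.ndarray) -> "ExpressionMatrix":
        """Row subset preserving order of ``idx``."""
        idx = np.asarray(idx)
        return ExpressionMatrix(
            values=self.values[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            labels=None if self.labels is None else self.labels[idx],
            mito_pct=None if self.mito_pct is None else self.mito_pct[idx],
        )

    def subset_genes(self, idx: np.ndarray) -> "ExpressionMatrix":
        """Column subset preserving order of ``idx``."""
        idx = np.asarray(idx)
        return ExpressionMatrix(
            values=self.values[:, idx],
            cell_ids=list(self.cell_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            labels=self.labels,
            mito_pct=self.mito_pct,
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same identifiers/annotations, new value matrix of equal shape."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("replacement values must keep the matrix shape")
        return replace(self, values=values)

    def with_labels(self, labels) -> "ExpressionMatrix":
        """Same values/identifiers with per-cell labels attached."""
        labels = np.asarray(labels)
        if labels.shape != (self.n_cells,):
            raise ValueError("labels must have one entry per cell")
        return replace(self, labels=labels)
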