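"""Matrix readers/writers (MatrixMarket and delimited text).

Conventions
-----------
* Matrices are cell-major: rows are cells, columns are genes; on-disk
  MTX files use the 1-based MatrixMarket coordinate standard.
* An MTX file ``X.mtx`` carries two sidecar text files ``X.cells.txt``
  and ``X.genes.txt``, one identifier per line, row/column order.
* Delimited tables (TSV/CSV) have a header row of gene IDs and a first
  column of cell IDs.

Integer count matrices round-trip bit-exactly through either format.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["read_matrix", "write_matrix", "read_labels", "write_labels"]


def _sidecar_paths(mtx_path: Path) -> tuple[Path, Path]:
    stem = mtx_path.with_suffix("")
    return Path(f"{stem}.cells.txt"), Path(f"{stem}.genes.txt")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("mtx", "tsv", "csv"):
        return suffix
    raise ValueError(f"cannot infer matrix format from {path.name!r}; pass format=")


def read_matrix(path, fmt: str | None = None) -> ExpressionMatrix:
    """Load an expression matrix with identifiers.

    ``fmt`` is one of ``mtx``/``tsv``/``csv`` (inferred from the file
    suffix when omitted).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        cells_path, genes_path = _sidecar_paths(path)
        for p in (cells_path, genes_path):
            if not p.exists():
                raise FileNotFoundError(f"missing sidecar identifier file {p}")
        try:
            values = sio.mmread(path)
        except ValueError as err:
            raise ValueError(f"malformed MatrixMarket file {path}: {err}") from err
        values = np.asarray(values.todense() if sparse.issparse(values) else values,
                            dtype=float)
        cells = cells_path.read_text().splitlines()
        genes = genes_path.read_text().splitlines()
        if len(cells) != values.shape[0]:
            raise ValueError(
                f"{cells_path.name}: {len(cells)} cell ids for "
                f"{values.shape[0]} matrix rows"
            )
        if len(genes) != values.shape[1]:
            raise ValueError(
                f"{genes_path.name}: {len(genes)} gene ids for "
                f"{values.shape[1]} matrix columns"
            )
        return ExpressionMatrix(values, cells, genes)
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_matrix(X: ExpressionMatrix, path, fmt: str | None = None) -> None:
    """Write a matrix (plus identifier sidecars for MTX)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        values = X.values
        is_int = np.all(values == np.round(values))
        coo = sparse.coo_matrix(values.astype(np.int64) if is_int else values)
        sio.mmwrite(path, coo, field="integer" if is_int else "real", precision=17)
        cells_path, genes_path = _sidecar_paths(path)
        cells_path.write_text("\n".join(X.cell_ids) + "\n")
        genes_path.write_text("\n".join(X.gene_ids) + "\n")
        return
    sep = "\t" if fmt == "tsv" else ","
    df = pd.DataFrame(X.values, index=X.cell_ids, columns=X.gene_ids)
    df.to_csv(path, sep=sep)


def read_labels(path) -> np.ndarray:
    """One label per line (or a two-column TSV of cell_id<TAB>label)."""
    lines = Path(path).read_text().splitlines()
    parts = [ln.split("\t") for ln in lines if ln]
    if parts and len(parts[0]) == 2:
        return np.asarray([p[1] for p in parts])
    return np.asarray([p[0] for p in parts])


def write_labels(labels, path) -> None:
    Path(path).write_text("\n".join(str(x) for x in labels) + "\n")
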