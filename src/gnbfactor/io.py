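"""Reading and writing count matrices, covariates and result tables.

Counts travel either as MatrixMarket sparse files (``.mtx``, with optional
``<stem>_genes.tsv`` / ``<stem>_cells.tsv`` label sidecars) or as delimited
text with a header row of cell identifiers and gene identifiers in the first
column.  Orientation on disk is genes x cells throughout; transposed input is
never guessed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .model import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_covariates",
    "select_hvg",
]


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}_genes.tsv"), Path(f"{stem}_cells.tsv")


def _read_labels(path: Path) -> list[str] | None:
    if path.exists():
        return [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return None


def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes x cells count matrix from ``.mtx`` or delimited text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty; expected a MatrixMarket or delimited count matrix")
    if path.suffix == ".mtx":
        mat = spio.mmread(path)
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        genes_p, cells_p = _sidecar_paths(path)
        return CountMatrix(dense, gene_ids=_read_labels(genes_p), cell_ids=_read_labels(cells_p))
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise ValueError(f"could not parse {path} as a delimited count matrix: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path} contains no data rows/columns")
    values = df.to_numpy()
    bad = ~np.isfinite(values.astype(float)) | ~np.isclose(values.astype(float), np.rint(values.astype(float)))
    if bad.any():
        v, j = [int(a[0]) for a in np.nonzero(bad)]
        raise ValueError(
            f"{path}: non-integer count at gene '{df.index[v]}', cell '{df.columns[j]}': {values[v, j]!r}"
        )
    if (values < 0).any():
        v, j = [int(a[0]) for a in np.nonzero(values < 0)]
        raise ValueError(
            f"{path}: negative count at gene '{df.index[v]}', cell '{df.columns[j]}': {values[v, j]!r}"
        )
    return CountMatrix(
        np.rint(values.astype(float)).astype(np.int64),
        gene_ids=list(df.index.astype(str)),
        cell_ids=list(df.columns.astype(str)),
    )


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    """Write counts as ``.mtx`` (+ label sidecars) or delimited text by suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(counts.counts))
        genes_p, cells_p = _sidecar_paths(path)
        genes_p.write_text("\n".join(counts.gene_ids) + "\n")
        cells_p.write_text("\n".join(counts.cell_ids) + "\n")
        return
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(counts.counts, index=counts.gene_ids, columns=counts.cell_ids)
    df.to_csv(path, sep=sep)


def read_covariates(path: str | Path) -> np.ndarray:
    """Read a covariate table (rows = cells or genes, first column = identifiers)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: covariates contain non-finite entries")
    return values


def select_hvg(counts: CountMatrix, n_genes: int) -> tuple[CountMatrix, np.ndarray]:
    """Keep the ``n_genes`` genes with largest variance of log(count + 1).

    Ties break stably by original row order.  Returns the filtered matrix and
    the boolean selection mask over the original genes.
    """
    if n_genes <= 0:
        raise ValueError(f"n_genes must be positive, got {n_genes}")
    V = counts.n_genes
    if n_genes > V:
        raise ValueError(f"n_genes={n_genes} exceeds the {V} genes present")
    var = np.var(np.log1p(counts.counts.astype(float)), axis=1)
    # stable: sort by (-variance, original index)
    order = np.lexsort((np.arange(V), -var))
    keep = np.sort(order[:n_genes])
    mask = np.zeros(V, dtype=bool)
    mask[keep] = True
    filtered = CountMatrix(
        counts.counts[keep],
        gene_ids=[counts.gene_ids[i] for i in keep],
        cell_ids=counts.cell_ids,
    )
    return filtered, mask
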