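"""Core containers and on-disk formats.

A cohort is represented as a triple: a sparse cell-by-gene integer count
matrix plus two tab-delimited sidecar tables annotating genes and cells.
On disk the matrix is Matrix Market coordinate format.  Both orientations
found in the wild (cells-as-rows and genes-as-rows) are accepted on read;
the writer always emits cells-as-rows and records the orientation in a
header comment.

Raw integer counts and log-normalized expression are kept as distinct,
immutable objects: the dominance score and the low-count spatial filter
are defined on raw counts, while sex/erythroid QC scores are defined on
log-normalized values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "GENE_COLUMNS",
    "CELL_COLUMNS",
    "OR_CLASSES",
    "MARKER_ROLES",
    "validate_gene_annotation",
    "validate_cell_annotation",
    "read_count_matrix",
    "write_count_matrix",
    "log_normalize",
    "subset_genes",
]

#: required columns of the gene sidecar table
GENE_COLUMNS = ("gene_id", "symbol", "is_or", "or_class", "chromosome", "marker_role")
#: required columns of the cell sidecar table (x/y present only for spatial cells)
CELL_COLUMNS = ("cell_id", "donor", "stage", "cell_type", "modality")

OR_CLASSES = ("I", "II", "none")
MARKER_ROLES = ("xist", "y_linked", "hemoglobin", "mitochondrial", "none")

_ORIENTATION_COMMENT = "rows=cells columns=genes"


@dataclass(frozen=True)
class CountMatrix:
    """Sparse cells x genes matrix of non-negative integer transcript counts."""

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    counts: sp.csr_matrix

    def __post_init__(self):
        cell_ids = np.asarray(self.cell_ids, dtype=object)
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        counts = sp.csr_matrix(self.counts)
        counts.sum_duplicates()
        if counts.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"matrix shape {counts.shape} does not match "
                f"{len(cell_ids)} cells x {len(gene_ids)} genes"
            )
        if len(set(cell_ids)) != len(cell_ids):
            raise ValueError("duplicate cell_ids")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene_ids")
        if counts.nnz:
            data = counts.data
            if np.any(data < 0):
                raise ValueError("negative counts are not allowed")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integral")
        counts = counts.astype(np.int64)
        object.__setattr__(self, "cell_ids", cell_ids)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "counts", counts)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def cell_totals(self) -> np.ndarray:
        """Total UMIs / transcripts per cell."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown gene id {e.args[0]!r}") from None

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(self.cell_ids[idx], self.gene_ids, self.counts[idx])


@dataclass(frozen=True)
class NormalizedMatrix:
    """Log-normalized expression on the same axes as a :class:`CountMatrix`.

    Values are ``log(1 + scale_factor * count / cell_total)``; a zero count
    maps exactly to a zero value, so sparsity is preserved.
    """

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    values: sp.csr_matrix
    scale_factor: float = 1e4

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        return CountMatrix.gene_index(self, gene_ids)  # same lookup logic


def validate_gene_annotation(genes: pd.DataFrame) -> pd.DataFrame:
    """Check the gene sidecar table and normalize dtypes in place."""
    missing = set(GENE_COLUMNS) - set(genes.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in gene annotation")
    genes = genes.copy()
    genes["is_or"] = genes["is_or"].astype(bool)
    bad_class = ~genes["or_class"].isin(OR_CLASSES)
    if bad_class.any():
        raise ValueError(f"invalid or_class values: {genes.loc[bad_class, 'or_class'].unique()}")
    bad_role = ~genes["marker_role"].isin(MARKER_ROLES)
    if bad_role.any():
        raise ValueError(f"invalid marker_role values: {genes.loc[bad_role, 'marker_role'].unique()}")
    # a gene carrying an OR class must be an OR gene
    if ((genes["or_class"] != "none") & ~genes["is_or"]).any():
        raise ValueError("or_class set on a gene with is_or=False")
    return genes


def validate_cell_annotation(cells: pd.DataFrame) -> pd.DataFrame:
    missing = set(CELL_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"cell annotation missing columns: {sorted(missing)}")
    if cells["cell_id"].duplicated().any():
        raise ValueError("duplicate cell_id in cell annotation")
    cells = cells.copy()
    spatial = cells["modality"] == "spatial"
    has_xy = {"x", "y"}.issubset(cells.columns)
    if spatial.any() and not has_xy:
        raise ValueError("spatial cells require x/y coordinate columns")
    if has_xy and spatial.any():
        if cells.loc[spatial, ["x", "y"]].isna().any().any():
            raise ValueError("spatial cells with missing coordinates")
    return cells


def read_count_matrix(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Read a cohort triple (Matrix Market matrix + gene/cell sidecars).

    The matrix orientation is resolved against the sidecar row counts; a
    matrix whose dimensions match neither orientation is rejected rather
    than silently truncated.
    """
    matrix_path, genes_path, cells_path = Path(matrix_path), Path(genes_path), Path(cells_path)
    for p in (matrix_path, genes_path, cells_path):
        if not p.exists():
            raise FileNotFoundError(str(p))
    genes = validate_gene_annotation(pd.read_csv(genes_path, sep="\t", dtype={"chromosome": str}))
    cells = validate_cell_annotation(pd.read_csv(cells_path, sep="\t"))
    mat = sp.coo_matrix(scipy.io.mmread(str(matrix_path)))
    n_cells, n_genes = len(cells), len(genes)
    if mat.shape == (n_cells, n_genes):
        pass
    elif mat.shape == (n_genes, n_cells) and n_genes != n_cells:
        mat = mat.T  # genes-as-rows dialect
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {n_cells} cells x "
            f"{n_genes} genes nor its transpose"
        )
    cm = CountMatrix(
        cells["cell_id"].to_numpy(object),
        genes["gene_id"].to_numpy(object),
        sp.csr_matrix(mat),
    )
    return cm, genes, cells


def write_count_matrix(
    cm: CountMatrix,
    genes: pd.DataFrame,
    cells: pd.DataFrame,
    out_dir: str | Path,
    prefix: str = "",
) -> dict[str, Path]:
    """Write the cohort triple; lossless under :func:`read_count_matrix`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = validate_gene_annotation(genes)
    cells = validate_cell_annotation(cells)
    if not np.array_equal(genes["gene_id"].to_numpy(object), cm.gene_ids):
        raise ValueError("gene annotation order does not match matrix columns")
    if not np.array_equal(cells["cell_id"].to_numpy(object), cm.cell_ids):
        raise ValueError("cell annotation order does not match matrix rows")
    paths = {
        "matrix": out_dir / f"{prefix}matrix.mtx",
        "genes": out_dir / f"{prefix}genes.tsv",
        "cells": out_dir / f"{prefix}cells.tsv",
    }
    scipy.io.mmwrite(
        str(paths["matrix"]),
        sp.coo_matrix(cm.counts),
        comment=_ORIENTATION_COMMENT,
        field="integer",
    )
    genes.to_csv(paths["genes"], sep="\t", index=False)
    cells.to_csv(paths["cells"], sep="\t", index=False)
    return paths


def log_normalize(cm: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Depth-scale each cell to ``scale_factor`` total and apply log1p.

    Cells with zero total counts yield all-zero rows rather than an error:
    such cells carry no information and are typically removed by QC anyway.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = cm.cell_totals().astype(float)
    csr = cm.counts.tocsr().astype(float)
    out = csr.copy()
    safe = np.where(totals > 0, totals, 1.0)
    row_scale = scale_factor / safe
    # scale nonzeros row-wise, then log1p (zero maps to zero, preserved)
    reps = np.diff(out.indptr)
    out.data = np.log1p(out.data * np.repeat(row_scale, reps))
    return NormalizedMatrix(cm.cell_ids, cm.gene_ids, out, scale_factor=scale_factor)


def subset_genes(
    cm: CountMatrix,
    genes: pd.DataFrame,
    predicate: Callable[[pd.DataFrame], pd.Series] | pd.Series | np.ndarray,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Column-subset the matrix by a predicate over the gene annotation.

    ``predicate`` is either a callable receiving the gene table and
    returning a boolean mask, or a precomputed mask.  Cell order and counts
    are unchanged; an empty selection warns but is not an error.
    """
    mask = predicate(genes) if callable(predicate) else predicate
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(genes),):
        raise ValueError("predicate mask length does not match gene annotation")
    if not mask.any():
        warnings.warn("gene predicate matched no genes; returning empty matrix", stacklevel=2)
    idx = np.flatnonzero(mask)
    sub = CountMatrix(cm.cell_ids, cm.gene_ids[idx], cm.counts[:, idx])
    return sub, genes.loc[mask].reset_index(drop=True)
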