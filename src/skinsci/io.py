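"""Sparse count-bundle I/O.

A count bundle is the plain-text trio commonly used for single-cell UMI
matrices: a Matrix-Market coordinate file (genes as rows, barcodes as
columns, integer values) plus two TSV annotation tables, ``genes.tsv``
(gene_id, gene_name) and ``cells.tsv`` (barcode, sample_id, genotype,
rt_index).  Matrix-Market is 1-based on disk; everything in memory is
0-based — the conversion happens only inside :func:`read_mtx_bundle` /
:func:`write_mtx_bundle` (delegated to ``scipy.io``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["CountMatrix", "read_mtx_bundle", "write_mtx_bundle", "merge_samples"]

CELL_COLUMNS = ["barcode", "sample_id", "genotype", "rt_index"]


@dataclass
class CountMatrix:
    """Gene x barcode UMI counts with gene and cell annotation tables.

    ``counts`` is a sparse nonnegative integer matrix with genes as rows.
    ``cells`` always carries the derived columns ``total_umis`` (column
    sums) and ``n_genes_detected`` (nonzero entries per column); they are
    recomputed, never trusted from input.
    """

    counts: sp.csr_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and (self.counts.data < 0).any():
            raise ValueError("counts must be nonnegative")
        n_genes, n_cells = self.counts.shape
        if len(self.genes) != n_genes:
            raise ValueError(
                f"gene table has {len(self.genes)} rows but counts matrix "
                f"has {n_genes} gene rows"
            )
        if len(self.cells) != n_cells:
            raise ValueError(
                f"cell table has {len(self.cells)} rows but counts matrix "
                f"has {n_cells} barcode columns"
            )
        if self.cells["barcode"].duplicated().any():
            dup = self.cells.loc[self.cells["barcode"].duplicated(), "barcode"].iloc[0]
            raise ValueError(f"duplicate barcode: {dup!r}")
        self.genes = self.genes.reset_index(drop=True)
        self.cells = self.cells.reset_index(drop=True)
        self._refresh_derived()

    def _refresh_derived(self) -> None:
        csc = self.counts.tocsc()
        self.cells["total_umis"] = np.asarray(csc.sum(axis=0)).ravel().astype(np.int64)
        self.cells["n_genes_detected"] = np.diff(csc.indptr).astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def total_umis(self) -> np.ndarray:
        return self.cells["total_umis"].to_numpy()

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        """Return a new CountMatrix restricted to the given barcode columns."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts.tocsc()[:, idx].tocsr(),
            genes=self.genes.copy(),
            cells=self.cells.iloc[idx].reset_index(drop=True).copy(),
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells as obs)."""
        import anndata

        return anndata.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cells.set_index("barcode"),
            var=self.genes.set_index("gene_id"),
        )


def read_mtx_bundle(matrix_path, genes_path, cells_path) -> CountMatrix:
    """Read a Matrix-Market count bundle.

    Derived per-cell columns are recomputed from the matrix.  Non-integer
    matrix values and annotation/matrix dimension mismatches are hard
    errors.
    """
    mat = scipy.io.mmread(os.fspath(matrix_path))
    mat = sp.coo_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError(f"{matrix_path}: matrix contains non-integer values")
    counts = sp.csr_matrix(
        (mat.data.astype(np.int64), (mat.row, mat.col)), shape=mat.shape
    )
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"{cells_path}: missing cell columns {missing}")
    if counts.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match annotations "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    return CountMatrix(counts=counts, genes=genes, cells=cells[CELL_COLUMNS].copy())


def write_mtx_bundle(cm: CountMatrix, out_dir, force: bool = False) -> dict:
    """Write ``matrix.mtx``, ``genes.tsv``, ``cells.tsv`` under ``out_dir``.

    Refuses to overwrite an existing bundle unless ``force``.  Triplets are
    written in row-major order so output is deterministic.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "matrix.mtx"),
        "genes": os.path.join(out_dir, "genes.tsv"),
        "cells": os.path.join(out_dir, "cells.tsv"),
    }
    if not force:
        for p in paths.values():
            if os.path.exists(p):
                raise FileExistsError(f"{p} exists; pass force=True to overwrite")
    coo = cm.counts.tocsr().tocoo()  # csr->coo gives row-major triplet order
    try:
        scipy.io.mmwrite(paths["matrix"], coo, field="integer")
        cm.genes[["gene_id", "gene_name"]].to_csv(paths["genes"], sep="\t", index=False)
        cm.cells[CELL_COLUMNS].to_csv(paths["cells"], sep="\t", index=False)
    except OSError as exc:  # pragma: no cover - exercised only on I/O failure
        raise OSError(f"failed writing bundle under {out_dir}: {exc}") from exc
    return paths


def merge_samples(matrices: list[CountMatrix]) -> CountMatrix:
    """Column-concatenate per-sample matrices sharing one gene table.

    Barcodes are prefixed with their sample_id so the merged barcode set is
    unique even when raw well barcodes collide across samples.
    """
    if not matrices:
        raise ValueError("need at least one CountMatrix")
    ref = matrices[0].genes[["gene_id", "gene_name"]].reset_index(drop=True)
    for m in matrices[1:]:
        other = m.genes[["gene_id", "gene_name"]].reset_index(drop=True)
        if len(other) != len(ref) or not ref["gene_id"].equals(other["gene_id"]):
            n = min(len(ref), len(other))
            neq = ref["gene_id"].values[:n] != other["gene_id"].values[:n]
            where = int(np.argmax(neq)) if neq.any() else n
            a = ref["gene_id"].values[where] if where < len(ref) else "<absent>"
            b = other["gene_id"].values[where] if where < len(other) else "<absent>"
            raise ValueError(
                f"gene tables differ at row {where}: {a!r} vs {b!r}"
            )
    cells = []
    for m in matrices:
        tab = m.cells.copy()
        tab["barcode"] = tab["sample_id"].astype(str) + ":" + tab["barcode"].astype(str)
        cells.append(tab[CELL_COLUMNS])
    merged = CountMatrix(
        counts=sp.hstack([m.counts for m in matrices], format="csr"),
        genes=ref.copy(),
        cells=pd.concat(cells, ignore_index=True),
    )
    return merged
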