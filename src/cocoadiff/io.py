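"""Readers and writers for sparse count matrices and per-cell metadata.

On-disk layout follows the 10x Genomics convention: a Matrix Market
coordinate file with genes as rows and cells as columns (1-based indices),
accompanied by ``genes.tsv`` and ``barcodes.tsv`` identifier lists.
Metadata tables are headered TSVs: ``(cell_id, individual_id[, cell_type])``
and ``(individual_id, label)`` with labels strictly in {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


@dataclass
class CellCountMatrix:
    """Sparse genes x cells matrix of non-negative integer counts."""

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        g, j = self.counts.shape
        if g != len(self.gene_ids):
            raise ValueError(
                f"matrix has {g} rows but {len(self.gene_ids)} gene ids"
            )
        if j != len(self.cell_ids):
            raise ValueError(
                f"matrix has {j} columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("negative count entries")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integer count entries")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, cell_index: np.ndarray) -> "CellCountMatrix":
        """Return a new matrix restricted to the given cell (column) indices."""
        cell_index = np.asarray(cell_index)
        return CellCountMatrix(
            counts=self.counts[:, cell_index],
            gene_ids=self.gene_ids,
            cell_ids=[self.cell_ids[i] for i in cell_index],
        )


@dataclass
class CellMeta:
    """Cell-to-individual assignment and per-individual binary disease label.

    ``individual_of`` maps every cell id to exactly one individual id;
    ``label_of`` maps every referenced individual to W in {0, 1}. Optional
    ``celltype_of`` carries a cell-type annotation per cell.
    """

    individual_of: dict[str, str]
    label_of: dict[str, int]
    celltype_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for ind, w in self.label_of.items():
            if w not in (0, 1):
                raise ValueError(f"label of individual {ind!r} is {w!r}, not in {{0,1}}")
        missing = {i for i in self.individual_of.values()} - set(self.label_of)
        if missing:
            raise ValueError(f"individuals without labels: {sorted(missing)[:5]}")

    def individuals(self) -> list[str]:
        """Individuals referenced by at least one cell, in stable order."""
        seen: dict[str, None] = {}
        for ind in self.individual_of.values():
            seen.setdefault(ind, None)
        return list(seen)

    def labels_present(self) -> set[int]:
        return {self.label_of[i] for i in self.individuals()}

    def cell_arrays(self, cell_ids: list[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Vectorized view aligned with ``cell_ids``.

        Returns (individual index per cell, label per cell, individual id list).
        """
        inds = sorted({self.individual_of[c] for c in cell_ids})
        ind_index = {ind: i for i, ind in enumerate(inds)}
        cell_ind = np.array([ind_index[self.individual_of[c]] for c in cell_ids])
        cell_w = np.array([self.label_of[self.individual_of[c]] for c in cell_ids])
        return cell_ind, cell_w, inds


@dataclass
class MarkerTable:
    """Binary genes x cell-types marker membership matrix."""

    L: np.ndarray
    gene_ids: list[str]
    type_names: list[str]

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L)
        if not np.isin(self.L, (0, 1)).all():
            raise ValueError("marker matrix entries must be 0/1")
        if self.L.shape != (len(self.gene_ids), len(self.type_names)):
            raise ValueError("marker matrix shape does not match id lists")
        empty = np.asarray(self.L.sum(axis=0) == 0).ravel()
        if empty.any():
            bad = [t for t, e in zip(self.type_names, empty) if e]
            raise ValueError(f"cell types without marker genes: {bad}")


def _read_ids(path: str | Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_count_matrix(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> CellCountMatrix:
    """Read a Matrix Market count matrix with gene/barcode identifier files.

    The coordinate file holds 1-based (gene, cell) indices with integer
    values; zero entries are never materialized.
    """
    m = scipy.io.mmread(str(matrix_path))
    m = sp.csr_matrix(m)
    m.eliminate_zeros()
    genes = _read_ids(genes_path)
    cells = _read_ids(barcodes_path)
    return CellCountMatrix(counts=m, gene_ids=genes, cell_ids=cells)


def write_count_matrix(cm: CellCountMatrix, out_dir: str | Path) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coo = cm.counts.tocoo()
    coo.data = np.round(coo.data).astype(np.int64)
    scipy.io.mmwrite(str(out / "matrix.mtx"), coo, field="integer")
    (out / "genes.tsv").write_text("".join(f"{g}\n" for g in cm.gene_ids))
    (out / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cm.cell_ids))


def read_cell_meta(
    cells_path: str | Path, labels_path: str | Path
) -> CellMeta:
    """Read the cell->individual and individual->label metadata TSVs."""
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)
    if "cell_id" not in cells.columns or "individual_id" not in cells.columns:
        raise ValueError("cell metadata must have columns (cell_id, individual_id[, cell_type])")
    if cells["cell_id"].duplicated().any():
        raise ValueError("a cell maps to more than one individual")
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    if "individual_id" not in labels.columns or "label" not in labels.columns:
        raise ValueError("label table must have columns (individual_id, label)")
    label_of = {}
    for ind, lab in zip(labels["individual_id"], labels["label"]):
        if lab not in ("0", "1"):
            raise ValueError(f"label {lab!r} for individual {ind!r} not in {{0,1}}")
        label_of[ind] = int(lab)
    celltype_of = None
    if "cell_type" in cells.columns:
        celltype_of = dict(zip(cells["cell_id"], cells["cell_type"]))
    return CellMeta(
        individual_of=dict(zip(cells["cell_id"], cells["individual_id"])),
        label_of=label_of,
        celltype_of=celltype_of,
    )


def write_cell_meta(meta: CellMeta, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = {"cell_id": list(meta.individual_of), "individual_id": list(meta.individual_of.values())}
    if meta.celltype_of is not None:
        rows["cell_type"] = [meta.celltype_of[c] for c in meta.individual_of]
    pd.DataFrame(rows).to_csv(out / "cells.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"individual_id": list(meta.label_of), "label": list(meta.label_of.values())}
    ).to_csv(out / "labels.tsv", sep="\t", index=False)


def read_marker_table(path: str | Path) -> MarkerTable:
    """Read a long-format marker TSV with columns (gene, cell_type)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene" not in df.columns or "cell_type" not in df.columns:
        raise ValueError("marker table must have columns (gene, cell_type)")
    genes = sorted(df["gene"].unique())
    types = sorted(df["cell_type"].unique())
    gi = {g: i for i, g in enumerate(genes)}
    ti = {t: i for i, t in enumerate(types)}
    L = np.zeros((len(genes), len(types)), dtype=np.int8)
    for g, t in zip(df["gene"], df["cell_type"]):
        L[gi[g], ti[t]] = 1
    return MarkerTable(L=L, gene_ids=genes, type_names=types)
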