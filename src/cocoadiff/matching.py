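"""Spectral embedding of cells and cross-condition k-nearest-neighbour search.

Each cell is matched to its nearest cells among those belonging to
individuals with the opposite disease label; the matched cells later serve
as counterfactual feature vectors.  Distances are Euclidean in a truncated
singular-value embedding of the (transformed) count matrix, computed once
over all cells jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.neighbors import NearestNeighbors

from .io import CellCountMatrix, CellMeta

#: above this cell count an approximate graph-based search is used
EXACT_KNN_LIMIT = 5000


@dataclass
class Embedding:
    """Cells x rank spectral coordinates (right singular vectors x values)."""

    coords: np.ndarray
    rank: int
    singular_values: np.ndarray
    cell_ids: list[str]


@dataclass
class MatchSet:
    """Per-cell matched opposite-condition cells with ascending distances."""

    indices: list[np.ndarray]
    distances: list[np.ndarray]
    k: int
    cell_ids: list[str]


def _transform(Y: sp.spmatrix, transform: str) -> sp.csc_matrix:
    X = sp.csc_matrix(Y, dtype=np.float64)
    if transform == "raw":
        return X
    X.data = np.log1p(X.data)
    if transform == "log1p":
        return X
    if transform == "log1p_unit":
        norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=0)).ravel())
        inv = np.where(norms > 0, 1.0 / np.maximum(norms, 1e-300), 0.0)
        return X @ sp.diags(inv)
    raise ValueError(f"unknown transform {transform!r}")


def embed_spectral(
    counts: CellCountMatrix,
    rank: int = 50,
    transform: str = "log1p_unit",
    seed: int = 0,
) -> Embedding:
    """Truncated SVD embedding of cells.

    The count matrix is entrywise log(1+Y)-transformed and each cell
    (column) scaled to unit L2 norm by default, making distances robust to
    sequencing depth; cell coordinates are the right singular vectors
    scaled by their singular values.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    max_rank = min(counts.n_genes, counts.n_cells)
    if rank > max_rank:
        warnings.warn(f"rank {rank} clipped to min(G, J) = {max_rank}")
        rank = max_rank
    X = _transform(counts.counts, transform)
    if rank >= max_rank:
        _, s, Vt = np.linalg.svd(np.asarray(X.todense()), full_matrices=False)
        s, Vt = s[:rank], Vt[:rank]
    else:
        # ARPACK with a seeded start vector: deterministic, near machine
        # precision even on flat spectra
        v0 = np.random.default_rng(seed).standard_normal(min(X.shape))
        _, s, Vt = svds(X, k=rank, v0=v0)
        order = np.argsort(s)[::-1]
        s, Vt = s[order], Vt[order]
    coords = Vt.T * s[None, :]
    return Embedding(coords=coords, rank=rank, singular_values=s, cell_ids=counts.cell_ids)


def _sorted_neighbors(dist_row: np.ndarray, idx_row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # ascending distance, ties broken by lower cell index
    order = np.lexsort((idx_row, dist_row))
    return idx_row[order], dist_row[order]


def match_opposite(
    embedding: Embedding,
    meta: CellMeta,
    k: int = 100,
    exact: bool | None = None,
    seed: int = 0,
) -> MatchSet:
    """k nearest opposite-condition cells for every cell.

    For a cell whose individual carries label w, candidates are all cells
    of individuals with label 1-w.  If fewer than k candidates exist, all
    are returned with a warning.  Exact brute-force search is used up to
    ``EXACT_KNN_LIMIT`` cells, a graph-based approximate search above.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = embedding.coords
    n = coords.shape[0]
    _, cell_w, _ = meta.cell_arrays(embedding.cell_ids)
    if len(set(cell_w.tolist())) < 2:
        raise ValueError("no opposite-condition cells: both labels must be present")
    if exact is None:
        exact = n <= EXACT_KNN_LIMIT

    indices: list[np.ndarray | None] = [None] * n
    distances: list[np.ndarray | None] = [None] * n
    for w in (0, 1):
        query_idx = np.where(cell_w == w)[0]
        cand_idx = np.where(cell_w == 1 - w)[0]
        if query_idx.size == 0:
            continue
        kk = min(k, cand_idx.size)
        if kk < k:
            warnings.warn(
                f"only {cand_idx.size} opposite-condition cells for label {w}; "
                f"returning {kk} matches instead of {k}"
            )
        if exact:
            nn = NearestNeighbors(n_neighbors=kk, algorithm="brute")
            nn.fit(coords[cand_idx])
            dist, loc = nn.kneighbors(coords[query_idx])
        else:
            from pynndescent import NNDescent

            index = NNDescent(
                coords[cand_idx],
                n_neighbors=min(max(kk + 10, 30), cand_idx.size),
                random_state=seed,
            )
            loc, dist = index.query(coords[query_idx], k=kk)
        for row, q in enumerate(query_idx):
            gi, gd = _sorted_neighbors(dist[row], cand_idx[loc[row]])
            indices[q] = gi
            distances[q] = gd
    return MatchSet(indices=indices, distances=distances, k=k, cell_ids=embedding.cell_ids)
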