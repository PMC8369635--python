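"""Individual-level pseudo-bulk expression.

Cells of an individual i share a gene mean λ_gi; a cell j contributes
counts Y_gj ~ Poisson(λ_gi ρ_j) where ρ_j is its sequencing depth.  Besides
the naive aggregates (total and mean over cells), a Poisson-Gamma
variational-Bayes estimate is provided: with Gamma(1, 1) priors on λ and ρ
the posterior means satisfy the coupled updates

    E[λ_gi] = (Σ_{j∈S_i} Y_gj + 1) / (Σ_{j∈S_i} E[ρ_j] + 1)
    E[ρ_j]  = (Σ_g Y_gj + 1) / (Σ_g E[λ_gi(j)] + 1)

iterated from E[ρ_j] = 1 until convergence; the unit pseudo-counts come
from the prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import CellCountMatrix, CellMeta


@dataclass
class PseudobulkSet:
    """Genes x individuals pseudo-bulk matrix with provenance."""

    lambda_hat: np.ndarray
    individual_ids: list[str]
    gene_ids: list[str]
    mode: str
    rho_hat: np.ndarray | None = None
    converged: bool = True
    n_iter: int = 0


def membership_matrix(cell_ind: np.ndarray, n_individuals: int) -> sp.csr_matrix:
    """Sparse cells x individuals 0/1 assignment matrix."""
    n_cells = cell_ind.shape[0]
    return sp.csr_matrix(
        (np.ones(n_cells), (np.arange(n_cells), cell_ind)),
        shape=(n_cells, n_individuals),
    )


def aggregate(counts: CellCountMatrix, meta: CellMeta, mode: str = "total") -> PseudobulkSet:
    """Naive pseudo-bulk: per-individual total or mean of cell counts."""
    if mode not in ("total", "mean"):
        raise ValueError(f"mode must be 'total' or 'mean', got {mode!r}")
    cell_ind, _, inds = meta.cell_arrays(counts.cell_ids)
    P = membership_matrix(cell_ind, len(inds))
    cells_per = np.asarray(P.sum(axis=0)).ravel()
    if np.any(cells_per == 0):
        raise ValueError("individual with zero cells")
    lam = np.asarray((counts.counts @ P).todense())
    if mode == "mean":
        lam = lam / cells_per[None, :]
    return PseudobulkSet(
        lambda_hat=lam, individual_ids=inds, gene_ids=counts.gene_ids, mode=mode
    )


def fit_poisson_gamma_vb(
    counts: CellCountMatrix,
    meta: CellMeta,
    max_iter: int = 100,
    tol: float = 1e-6,
    prior: float = 1.0,
) -> PseudobulkSet:
    """Poisson-Gamma variational Bayes pseudo-bulk estimate.

    Alternates the λ and ρ posterior-mean updates until the maximum
    relative change of both blocks drops below ``tol``.  ``prior`` is the
    Gamma(a, a) hyperparameter entering as the pseudo-count (default 1;
    values near 0 weaken the prior but can destabilize shallow samples).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    Y = counts.counts.tocsr()
    cell_ind, _, inds = meta.cell_arrays(counts.cell_ids)
    n_ind = len(inds)
    P = membership_matrix(cell_ind, n_ind)
    if np.any(np.asarray(P.sum(axis=0)).ravel() == 0):
        raise ValueError("individual with zero cells")

    ysum_gi = np.asarray((Y @ P).todense())          # Σ_{j∈S_i} Y_gj
    ysum_j = np.asarray(Y.sum(axis=0)).ravel()       # Σ_g Y_gj

    rho = np.ones(counts.n_cells)
    lam = np.empty((counts.n_genes, n_ind))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rho_sum_i = P.T @ rho                         # Σ_{j∈S_i} E[ρ_j]
        lam_new = (ysum_gi + prior) / (rho_sum_i + prior)[None, :]
        lam_sum_i = lam_new.sum(axis=0)               # Σ_g E[λ_gi]
        rho_new = (ysum_j + prior) / (lam_sum_i[cell_ind] + prior)
        if it > 1:
            dl = np.max(np.abs(lam_new - lam) / np.maximum(np.abs(lam), 1e-300))
            dr = np.max(np.abs(rho_new - rho) / np.maximum(np.abs(rho), 1e-300))
            if max(dl, dr) < tol:
                lam, rho = lam_new, rho_new
                converged = True
                break
        lam, rho = lam_new, rho_new
    return PseudobulkSet(
        lambda_hat=lam,
        individual_ids=inds,
        gene_ids=counts.gene_ids,
        mode="bayes",
        rho_hat=rho,
        converged=converged,
        n_iter=it,
    )
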