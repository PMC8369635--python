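"""Decomposition of pseudo-bulk means into confounder and disease effect.

The pseudo-bulk mean factorizes as λ_gi = μ_gi δ_gi.  The confounder μ_gi
is label-invariant: it is estimated from each cell's observed profile
Y^(w) together with its imputed counterfactual profile Ŷ^(1-w), each with
its own condition-specific depth ρ_j^(w), under

    Y_gj^(w) ~ Poisson(μ_gi ρ_j^(w)),  w ∈ {0, 1}.

With Gamma(1,1) priors, variational posterior means alternate

    E[μ_gi]    = (1 + Σ_w Σ_{j∈S_i} Y_gj^(w)) / (1 + Σ_w Σ_{j∈S_i} E[ρ_j^(w)])
    E[ρ_j^(w)] = (1 + Σ_g Y_gj^(w)) / (1 + Σ_g E[μ_gi(j)])

Fixing μ̂ at its posterior mean, the residual disease effect δ_gi is
recovered from the observed cells only, Y_gj ~ Poisson(μ̂_gi δ_gi ρ_j):

    E[δ_gi] = (1 + Σ_j Y_gj) / (1 + μ̂_gi Σ_j E[ρ_j])
    E[ρ_j]  = (1 + Σ_g Y_gj) / (1 + Σ_g μ̂_gi E[δ_gi])

and, since δ is Gamma under the variational posterior,

    E[ln δ_gi] = ψ(1 + Σ_j Y_gj) − ln(1 + μ̂_gi Σ_j E[ρ_j])
    V[ln δ_gi] = (Σ_j Y_gj)^{-1}

with the ln-scale summaries reported only where the individual has at
least one read on the gene (the Gaussian approximation of the Gamma
posterior needs α > 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import psi

from .counterfactual import CounterfactualCounts
from .io import CellCountMatrix, CellMeta
from .pseudobulk import membership_matrix


@dataclass
class CocoaDecomposition:
    """Per gene x individual confounder μ and residual disease effect δ."""

    mu: np.ndarray
    delta: np.ndarray
    ln_delta_mean: np.ndarray
    ln_delta_var: np.ndarray
    rho_w: np.ndarray  # (2, n_cells): [observed side, counterfactual side]
    rho: np.ndarray
    individual_ids: list[str]
    gene_ids: list[str]
    converged: bool = True

    def to_frame(self):
        """Long-format table keyed by (gene, individual)."""
        import pandas as pd

        G, n = self.mu.shape
        return pd.DataFrame(
            {
                "gene": np.repeat(self.gene_ids, n),
                "individual": np.tile(self.individual_ids, G),
                "mu": self.mu.ravel(),
                "delta": self.delta.ravel(),
                "ln_delta_mean": self.ln_delta_mean.ravel(),
                "ln_delta_var": self.ln_delta_var.ravel(),
            }
        )


def estimate_confounder(
    counts: CellCountMatrix,
    counterfactual: CounterfactualCounts,
    meta: CellMeta,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[str], bool]:
    """Label-invariant confounder μ_gi shared by observed and imputed cells.

    Returns ``(mu, rho_w, individual_ids, converged)`` where ``rho_w`` is a
    (2, n_cells) array: row 0 holds the depth of each cell's observed
    profile (condition w of the cell), row 1 the depth of its imputed
    counterfactual profile (condition 1-w).  The imputed values enter the
    Poisson updates only through their sufficient-statistic sums, so they
    need not be integers.
    """
    Y = counts.counts.tocsr()
    yhat = counterfactual.yhat
    if yhat.shape != Y.shape:
        raise ValueError("counterfactual matrix not aligned with counts")
    cell_ind, _, inds = meta.cell_arrays(counts.cell_ids)
    n_ind = len(inds)
    P = membership_matrix(cell_ind, n_ind)
    if np.any(np.asarray(P.sum(axis=0)).ravel() == 0):
        raise ValueError("individual with zero cells")

    num_gi = 1.0 + np.asarray((Y @ P).todense()) + yhat @ np.asarray(P.todense())
    ysum_obs = np.asarray(Y.sum(axis=0)).ravel()
    ysum_cf = yhat.sum(axis=0)

    rho_obs = np.ones(counts.n_cells)
    rho_cf = np.ones(counts.n_cells)
    mu = np.empty((counts.n_genes, n_ind))
    converged = False
    for it in range(1, max_iter + 1):
        rho_sum_i = P.T @ (rho_obs + rho_cf)
        mu_new = num_gi / (1.0 + rho_sum_i)[None, :]
        mu_sum_i = mu_new.sum(axis=0)[cell_ind]
        rho_obs_new = (1.0 + ysum_obs) / (1.0 + mu_sum_i)
        rho_cf_new = (1.0 + ysum_cf) / (1.0 + mu_sum_i)
        if it > 1:
            dm = np.max(np.abs(mu_new - mu) / np.maximum(mu, 1e-300))
            dr = np.max(np.abs(rho_obs_new - rho_obs) / np.maximum(rho_obs, 1e-300))
            dc = np.max(np.abs(rho_cf_new - rho_cf) / np.maximum(rho_cf, 1e-300))
            if max(dm, dr, dc) < tol:
                mu, rho_obs, rho_cf = mu_new, rho_obs_new, rho_cf_new
                converged = True
                break
        mu, rho_obs, rho_cf = mu_new, rho_obs_new, rho_cf_new
    return mu, np.vstack([rho_obs, rho_cf]), inds, converged


def estimate_residual(
    counts: CellCountMatrix,
    mu: np.ndarray,
    meta: CellMeta,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Residual disease effect δ_gi with μ̂ fixed to its posterior mean.

    Returns ``(delta, ln_delta_mean, ln_delta_var, rho, converged)``.
    (g, i) pairs with zero reads over the individual's cells have
    ``E[δ]`` defined through the pseudo-counts but NaN ln-scale summaries.
    """
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        raise ValueError("mu must be strictly positive and finite")
    Y = counts.counts.tocsr()
    cell_ind, _, inds = meta.cell_arrays(counts.cell_ids)
    n_ind = len(inds)
    if mu.shape != (counts.n_genes, n_ind):
        raise ValueError("mu not aligned with counts/meta")
    P = membership_matrix(cell_ind, n_ind)

    ysum_gi = np.asarray((Y @ P).todense())
    ysum_j = np.asarray(Y.sum(axis=0)).ravel()

    rho = np.ones(counts.n_cells)
    delta = np.empty_like(mu)
    converged = False
    for it in range(1, max_iter + 1):
        rho_sum_i = P.T @ rho
        delta_new = (1.0 + ysum_gi) / (1.0 + mu * rho_sum_i[None, :])
        denom_j = (mu * delta_new).sum(axis=0)[cell_ind]
        rho_new = (1.0 + ysum_j) / (1.0 + denom_j)
        if it > 1:
            dd = np.max(np.abs(delta_new - delta) / np.maximum(delta, 1e-300))
            dr = np.max(np.abs(rho_new - rho) / np.maximum(rho, 1e-300))
            if max(dd, dr) < tol:
                delta, rho = delta_new, rho_new
                converged = True
                break
        delta, rho = delta_new, rho_new

    rho_sum_i = P.T @ rho
    ln_mean = psi(1.0 + ysum_gi) - np.log(1.0 + mu * rho_sum_i[None, :])
    with np.errstate(divide="ignore"):
        ln_var = 1.0 / ysum_gi
    missing = ysum_gi == 0
    ln_mean[missing] = np.nan
    ln_var[missing] = np.nan
    return delta, ln_mean, ln_var, rho, converged


def decompose(
    counts: CellCountMatrix,
    counterfactual: CounterfactualCounts,
    meta: CellMeta,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> CocoaDecomposition:
    """Run both estimation stages and bundle the results."""
    mu, rho_w, inds, conv1 = estimate_confounder(
        counts, counterfactual, meta, max_iter=max_iter, tol=tol
    )
    delta, ln_mean, ln_var, rho, conv2 = estimate_residual(
        counts, mu, meta, max_iter=max_iter, tol=tol
    )
    return CocoaDecomposition(
        mu=mu,
        delta=delta,
        ln_delta_mean=ln_mean,
        ln_delta_var=ln_var,
        rho_w=rho_w,
        rho=rho,
        individual_ids=inds,
        gene_ids=counts.gene_ids,
        converged=conv1 and conv2,
    )
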