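"""Generative model for confounded case-control single-cell count data.

Individual-level covariates split into confounders X (which bias both the
disease label and expression) and batch effects B (expression only):

    X_ik, B_il ~ N(0, 1)
    W_i ~ Bernoulli(sigmoid(Σ_k X_ik α_k + ε_{W,i}))
    ln λ_gi = τ_g W_i + Σ_k X_ik β_kg + Σ_l B_il γ_lg + ε_λ

with β_kg, γ_lg ~ N(0, σ²_{X,B→Y}/(d_C+d_B)), τ_g ~ N(0, σ²_{W→Y}) on the
causal genes only (zero elsewhere), and ε_λ ~ N(0, 1−σ²_{X,B→Y}−σ²_{W→Y}).
The noise ε_W is rescaled so the realized variance ratio
V[Xα]/V[Xα+ε_W] equals σ²_{X→W} exactly.  Cells then draw a sequencing
depth ρ_j ~ Gamma(6.25, 6.25) (unit mean) and counts
Y_gj ~ Poisson(λ_gi ρ_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import CellCountMatrix, CellMeta


@dataclass
class SimConfig:
    """Study-design parameters of a simulated case-control cohort."""

    n_genes: int = 10_000
    n_causal: int = 50
    n_individuals: int = 40
    cells_per_individual: float = 50.0
    d_confounders: int = 5
    d_batch: int = 0
    var_xw: float = 0.5   # variance of the label logit explained by X
    var_wy: float = 0.3   # variance of ln λ explained by W (causal genes)
    var_xby: float = 0.5  # variance of ln λ explained by X and B
    depth_shape: float = 6.25
    depth_rate: float = 6.25
    fixed_cells: bool = False  # exact cells_per_individual instead of Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.var_xw < 1 and 0 <= self.var_wy < 1 and 0 <= self.var_xby < 1):
            raise ValueError("variance fractions must lie in [0, 1)")
        if self.var_xby + self.var_wy >= 1:
            raise ValueError("var_xby + var_wy must be < 1 (residual variance)")
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.d_confounders < 1:
            raise ValueError("need at least one confounding variable")
        if not (0 <= self.n_causal <= self.n_genes):
            raise ValueError("n_causal out of range")


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    X: np.ndarray
    B: np.ndarray
    W: np.ndarray
    alpha: np.ndarray
    tau: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    lam: np.ndarray
    rho: np.ndarray
    causal_flags: np.ndarray
    confound_effect: np.ndarray = field(default=None)  # genes x individuals Σ_k X_ik β_kg
    unconfounded_logmean: np.ndarray = field(default=None)  # ln λ − confounding part


def simulate_individuals(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw covariates, disease labels, and the label-bias coefficients.

    ε_W is orthogonalized against Xα and rescaled so that the realized
    (sample) variance ratio V[Xα]/V[Xα+ε_W] equals var_xw exactly.
    Returns ``(X, B, W, alpha, logit)`` with the realized label logits
    Xα + ε_W included for verifiability.
    """
    n = config.n_individuals
    X = rng.standard_normal((n, config.d_confounders))
    B = rng.standard_normal((n, config.d_batch))
    alpha = rng.standard_normal(config.d_confounders)
    eps = rng.standard_normal(n)
    if config.var_xw == 0:
        alpha = np.zeros_like(alpha)
        logit = eps
    else:
        u = X @ alpha
        uc = u - u.mean()
        # remove the sample covariance with u, then scale the remainder
        e = eps - eps.mean()
        e = e - (e @ uc) / (uc @ uc) * uc
        vu = uc.var()
        ve = e.var()
        scale = np.sqrt(vu * (1.0 - config.var_xw) / (config.var_xw * ve))
        logit = u + scale * e
    W = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit))).astype(np.int8)
    return X, B, W, alpha, logit


def simulate_lambda(
    X: np.ndarray,
    B: np.ndarray,
    W: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Individual-level gene means from the log-linear generative model.

    Returns ``(lam, tau, beta, gamma, causal_flags)`` with ``lam`` of shape
    genes x individuals; τ_g is zero on non-causal genes.
    """
    G, n = config.n_genes, config.n_individuals
    d_tot = config.d_confounders + config.d_batch
    causal = np.zeros(G, dtype=bool)
    causal[rng.choice(G, size=config.n_causal, replace=False)] = True
    tau = np.zeros(G)
    tau[causal] = rng.normal(0.0, np.sqrt(config.var_wy), size=config.n_causal)
    sd_cov = np.sqrt(config.var_xby / d_tot)
    beta = rng.normal(0.0, sd_cov, size=(config.d_confounders, G))
    gamma = rng.normal(0.0, sd_cov, size=(config.d_batch, G))
    resid_sd = np.sqrt(1.0 - config.var_xby - config.var_wy)
    eps = rng.normal(0.0, resid_sd, size=(G, n))
    log_lam = tau[:, None] * W[None, :] + beta.T @ X.T + gamma.T @ B.T + eps
    return np.exp(log_lam), tau, beta, gamma, causal


def simulate_cells(
    lam: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[CellCountMatrix, np.ndarray, np.ndarray]:
    """Cell-level counts: ρ_j ~ Gamma(shape, rate), Y_gj ~ Poisson(λ_gi ρ_j).

    Returns the count matrix, the individual index of each cell, and the
    per-cell depths ρ.
    """
    G, n = lam.shape
    if config.fixed_cells:
        n_cells = np.full(n, int(round(config.cells_per_individual)))
    else:
        n_cells = np.maximum(1, rng.poisson(config.cells_per_individual, size=n))
    cell_ind = np.repeat(np.arange(n), n_cells)
    J = cell_ind.size
    rho = rng.gamma(config.depth_shape, 1.0 / config.depth_rate, size=J)
    rate = lam[:, cell_ind] * rho[None, :]
    Y = sp.csr_matrix(rng.poisson(rate))
    gene_ids = [f"g{g:05d}" for g in range(G)]
    cell_ids = [f"cell{j:06d}" for j in range(J)]
    cm = CellCountMatrix(counts=Y, gene_ids=gene_ids, cell_ids=cell_ids)
    return cm, cell_ind, rho


def simulate_dataset(config: SimConfig) -> tuple[CellCountMatrix, CellMeta, SimTruth]:
    """Full cohort simulation; everything is a function of (config, seed)."""
    rng = np.random.default_rng(config.seed)
    X, B, W, alpha, _ = simulate_individuals(config, rng)
    lam, tau, beta, gamma, causal = simulate_lambda(X, B, W, config, rng)
    cm, cell_ind, rho = simulate_cells(lam, config, rng)
    ind_ids = [f"ind{i:03d}" for i in range(config.n_individuals)]
    meta = CellMeta(
        individual_of={c: ind_ids[i] for c, i in zip(cm.cell_ids, cell_ind)},
        label_of={ind_ids[i]: int(W[i]) for i in range(config.n_individuals)},
    )
    confound = beta.T @ X.T  # genes x individuals
    truth = SimTruth(
        X=X, B=B, W=W, alpha=alpha, tau=tau, beta=beta, gamma=gamma,
        lam=lam, rho=rho, causal_flags=causal,
        confound_effect=confound,
        unconfounded_logmean=np.log(lam) - confound,
    )
    return cm, meta, truth
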