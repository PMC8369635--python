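"""Marker-constrained mixture of von Mises-Fisher distributions.

Each cell's marker-gene profile is reduced to a unit vector m_j; cell
types are directions θ_k on the sphere, constrained to be supported only
on their own marker genes (the binary label matrix L), with one shared
concentration κ.  A stochastic EM alternates sampling hard assignments
z_j ∝ exp(κ m_j·θ_k) with the constrained mean update

    θ_k ← (Σ_j z_jk m_j ∘ l_k) / ‖Σ_j z_jk m_j ∘ l_k‖

and the closed-form concentration κ ← (r d − r³)/(1 − r²) where
r = ‖Σ_j m_j‖ / n is the global resultant length (assignment-independent,
so κ is set once from the data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import CellCountMatrix, MarkerTable

_R_CAP = 1.0 - 1e-8


@dataclass
class VmfModel:
    """Fitted constrained vMF mixture."""

    theta: np.ndarray          # d x K unit mean directions
    kappa: float
    assignments: np.ndarray    # modal cell-type index per usable cell (-1 unassigned)
    r: float
    type_names: list[str]
    marker_genes: list[str]
    usable: np.ndarray         # mask over input cells (non-zero marker profile)
    scores: np.ndarray         # cells x K cosine similarities at the final theta


def kappa_closed_form(r: float, d: int) -> float:
    """Concentration estimate κ = (r d − r³)/(1 − r²), r capped below 1."""
    r = min(max(float(r), 0.0), _R_CAP)
    return (r * d - r**3) / (1.0 - r**2)


def normalize_marker_features(
    counts: CellCountMatrix, markers: MarkerTable
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Unit-norm log(1+Y) marker-gene profiles per cell.

    Restricts to marker genes present in the count matrix.  Returns
    ``(M, usable, marker_genes)`` where M is cells x d with unit rows for
    usable cells; cells with all-zero marker counts are flagged unusable
    (zero rows) and excluded from EM.
    """
    gene_index = {g: i for i, g in enumerate(counts.gene_ids)}
    keep = [g for g in markers.gene_ids if g in gene_index]
    if not keep:
        raise ValueError("no marker genes present in the count matrix")
    rows = [gene_index[g] for g in keep]
    sub = sp.csr_matrix(counts.counts[rows, :], dtype=np.float64)
    sub.data = np.log1p(sub.data)
    M = np.asarray(sub.T.todense())  # cells x d
    norms = np.linalg.norm(M, axis=1)
    usable = norms > 0
    M[usable] /= norms[usable, None]
    return M, usable, keep


def _restrict_markers(markers: MarkerTable, keep: list[str]) -> np.ndarray:
    idx = {g: i for i, g in enumerate(markers.gene_ids)}
    return markers.L[[idx[g] for g in keep], :].astype(float)


def fit_vmf_mixture(
    M: np.ndarray,
    markers: MarkerTable,
    marker_genes: list[str] | None = None,
    usable: np.ndarray | None = None,
    n_steps: int = 100,
    burn_in: int = 50,
    collect_last: int = 10,
    seed: int = 0,
    kappa_in_estep: bool = True,
) -> VmfModel:
    """Stochastic EM for the marker-constrained vMF mixture.

    ``M`` is cells x d of unit vectors (d marker genes, ordered as
    ``marker_genes``, default the marker table's gene order).  The E-step
    samples assignments from the discrete distribution ∝ exp(κ m·θ)
    (``kappa_in_estep=False`` drops κ from the sampling weights); the
    modal assignment over the last ``collect_last`` E-steps is returned.
    Empty clusters are reinitialized at their marker centroid.
    """
    if markers.L.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if marker_genes is None:
        marker_genes = list(markers.gene_ids)
    L = _restrict_markers(markers, marker_genes)  # d x K
    d, K = L.shape
    if M.shape[1] != d:
        raise ValueError("M not aligned with marker genes")
    if usable is None:
        usable = np.linalg.norm(M, axis=1) > 0
    Mu = M[usable]
    n = Mu.shape[0]
    if n == 0:
        raise ValueError("no usable cells")
    rng = np.random.default_rng(seed)

    r = np.linalg.norm(Mu.sum(axis=0)) / n
    kappa = kappa_closed_form(r, d)

    def marker_centroid(k: int) -> np.ndarray:
        v = L[:, k].copy()
        return v / np.linalg.norm(v)

    theta = np.column_stack([marker_centroid(k) for k in range(K)])
    votes = np.zeros((n, K), dtype=np.int64)
    collect_from = max(n_steps - collect_last, min(burn_in, n_steps - 1))
    z = np.zeros(n, dtype=np.int64)
    for step in range(n_steps):
        # E-step: sample hard assignments
        logits = Mu @ theta
        if kappa_in_estep:
            logits = kappa * logits
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random((n, 1))
        z = (p.cumsum(axis=1) < u).sum(axis=1)
        z = np.minimum(z, K - 1)
        if step >= collect_from:
            votes[np.arange(n), z] += 1
        # M-step: constrained mean directions
        for k in range(K):
            members = z == k
            if not members.any():
                warnings.warn(f"empty cluster {k}; reinitializing from marker centroid")
                theta[:, k] = marker_centroid(k)
                continue
            v = Mu[members].sum(axis=0) * L[:, k]
            nv = np.linalg.norm(v)
            if nv == 0:
                theta[:, k] = marker_centroid(k)
            else:
                theta[:, k] = v / nv

    modal = votes.argmax(axis=1)
    assignments = np.full(M.shape[0], -1, dtype=np.int64)
    assignments[usable] = modal
    scores = M @ theta
    return VmfModel(
        theta=theta,
        kappa=float(kappa),
        assignments=assignments,
        r=float(r),
        type_names=list(markers.type_names),
        marker_genes=list(marker_genes),
        usable=usable,
        scores=scores,
    )


def annotate_cells(
    counts: CellCountMatrix,
    markers: MarkerTable,
    n_steps: int = 100,
    seed: int = 0,
) -> dict[str, str]:
    """Convenience wrapper: cell_id -> cell-type name (unassignable cells omitted)."""
    M, usable, keep = normalize_marker_features(counts, markers)
    model = fit_vmf_mixture(
        M, markers, marker_genes=keep, usable=usable, n_steps=n_steps, seed=seed
    )
    out = {}
    for cid, a in zip(counts.cell_ids, model.assignments):
        if a >= 0:
            out[cid] = model.type_names[a]
    return out
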