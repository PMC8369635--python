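"""Gene-level testing, effect summarization, and evaluation metrics.

Genes are ranked by a two-sided Wilcoxon rank-sum test comparing a
per-individual statistic between cases and controls.  Model-based effect
sizes come from a Gaussian approximation of the Gamma posterior of ln δ:
per-individual (η_i, σ_i²) are combined across individuals by
inverse-variance weighting into a gene-level average disease effect (ADE)
with standard error (SE), and a Wald Z.  AUPRC and empirical FDR evaluate
rankings against known causal flags in simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GaussApprox:
    """Gaussian approximation of ln λ for λ ~ Gamma(α, β)."""

    mean: float
    var: float


def wilcoxon_ranksum(values_case, values_ctrl) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Missing values are dropped.  The exact null distribution is used when
    n1 + n2 <= 12 and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  Returns NaN when
    either group is empty.
    """
    x = np.asarray(values_case, dtype=float)
    y = np.asarray(values_ctrl, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        return np.nan
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def wilcoxon_matrix(values: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for a genes x individuals matrix.

    Uses the tie/continuity-corrected normal approximation (the sample
    sizes of a case-control panel put every gene on the asymptotic
    branch).  Rows where either group is all-missing get NaN.
    """
    is_case = np.asarray(is_case, dtype=bool)
    case = values[:, is_case]
    ctrl = values[:, ~is_case]
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(
            case, ctrl, alternative="two-sided", method="asymptotic",
            axis=1, nan_policy="omit",
        )
    return np.asarray(res.pvalue, dtype=float)


def gamma_log_gaussian(alpha: float, beta: float) -> GaussApprox:
    """Local Gaussian approximation of ln λ, λ ~ Gamma(α, β).

    Quadratic expansion at the mode for α > 1 gives
    N(ln((α−1)/β), (α−1)^{-1}); for 0 < α <= 1 the expansion point moves
    to the mean, giving N(ln(α/β), α^{-1}).
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if alpha > 1:
        return GaussApprox(mean=float(np.log((alpha - 1) / beta)), var=1.0 / (alpha - 1))
    return GaussApprox(mean=float(np.log(alpha / beta)), var=1.0 / alpha)


def meta_average(etas, variances) -> tuple[float, float]:
    """Inverse-variance-weighted mean and its variance.

    η̄ = Σ η_i/σ_i² / Σ 1/σ_i²,  σ̄² = 1 / Σ 1/σ_i².
    """
    etas = np.asarray(etas, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if etas.size == 0 or etas.shape != variances.shape:
        raise ValueError("etas and variances must be equal-length and non-empty")
    if np.any(variances <= 0):
        raise ValueError("variances must be positive")
    w = 1.0 / variances
    return float((etas * w).sum() / w.sum()), float(1.0 / w.sum())


def ade_se(
    ln_delta_mean: np.ndarray,
    ln_delta_var: np.ndarray,
    z_mode: str = "wald",
) -> tuple[float, float, np.ndarray]:
    """Gene-level average disease effect, standard error, per-individual Z.

    NaN individuals (no reads) are excluded from the meta-analysis.
    ``z_mode='wald'`` standardizes per-individual effects as E/√V;
    ``'ev_ratio'`` uses the E/V form.  Returns (ADE, SE, Z_i); all-missing
    input yields (nan, nan, Z_i).
    """
    eta = np.asarray(ln_delta_mean, dtype=float)
    var = np.asarray(ln_delta_var, dtype=float)
    ok = np.isfinite(eta) & np.isfinite(var) & (var > 0)
    if z_mode == "wald":
        z = np.where(ok, eta / np.sqrt(np.where(ok, var, 1.0)), np.nan)
    elif z_mode == "ev_ratio":
        z = np.where(ok, eta / np.where(ok, var, 1.0), np.nan)
    else:
        raise ValueError(f"unknown z_mode {z_mode!r}")
    if not ok.any():
        return np.nan, np.nan, z
    ade, var_bar = meta_average(eta[ok], var[ok])
    return ade, float(np.sqrt(var_bar)), z


def storey_qvalues(p_values: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the fixed-λ π0 estimator.

    π̂0 = #{p > λ} / ((1 − λ) m), capped at 1; q is the π0-scaled BH
    step-up quantity made monotone from the largest p downward.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    pi0 = min(1.0, (p > lam).sum() / ((1.0 - lam) * m)) if m else 1.0
    pi0 = max(pi0, 1.0 / m) if m else 1.0
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def adjust_multiplicity(p_values, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: 'bh', 'storey_q', 'bonferroni' or 'holm'."""
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] <= 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    out = np.full(p.shape, np.nan)
    pf = p[finite]
    if pf.size == 0:
        return out
    if method == "bh":
        out[finite] = multipletests(pf, method="fdr_bh")[1]
    elif method == "storey_q":
        out[finite] = storey_qvalues(pf)
    elif method == "bonferroni":
        out[finite] = multipletests(pf, method="bonferroni")[1]
    elif method == "holm":
        out[finite] = multipletests(pf, method="holm")[1]
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def auprc(scores, causal_flags) -> float:
    """Area under the precision-recall curve, trapezoidal, ties averaged.

    Scores are ranked descending; tied scores form a single curve point
    (equivalently the average over tie-breaking orders).  The curve is
    anchored at recall 0 with the precision of the first distinct score
    group.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(causal_flags).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and flags must align")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("need at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s = s[order]
    y = y[order]
    # indices where a tie group ends
    boundary = np.nonzero(np.diff(s))[0]
    ends = np.concatenate([boundary, [s.size - 1]])
    tp = np.cumsum(y)[ends]
    n_at = ends + 1.0
    precision = tp / n_at
    recall = tp / n_pos
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    return float(np.trapezoid(precision, recall))


def empirical_fdr(q_values, causal_flags, cutoff: float = 0.01) -> float:
    """Fraction of non-causal genes among q < cutoff discoveries (0 if none)."""
    q = np.asarray(q_values, dtype=float)
    y = np.asarray(causal_flags).astype(bool)
    disc = q < cutoff
    n_disc = int(disc.sum())
    if n_disc == 0:
        return 0.0
    return float((~y[disc]).sum() / n_disc)
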