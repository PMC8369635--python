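"""End-to-end pipeline: embed, match, impute, decompose, test.

When a cell-type annotation is present the whole pipeline (including the
matching step) runs independently inside each cell type, since confounder
structure may be cell-type-specific; a stratum whose individuals carry
only one label violates the overlap assumption and is skipped with a
warning.  Output is one row per gene per stratum with the rank-sum
p-value, its BH-adjusted q, and the meta-analytic effect summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .cocoa import CocoaDecomposition, decompose
from .counterfactual import impute_counterfactual
from .inference import adjust_multiplicity, wilcoxon_matrix
from .io import CellCountMatrix, CellMeta
from .matching import embed_spectral, match_opposite

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable knobs of the end-to-end analysis."""

    rank: int = 50
    knn: int = 100
    transform: str = "log1p_unit"
    impute_method: str = "poisson_reg"
    k_use: int | None = None
    ridge: float = 1e-4
    max_iter: int = 100
    tol: float = 1e-6
    impute_tol: float = 1e-4
    q_method: str = "bh"
    z_mode: str = "wald"
    seed: int = 0


def ade_table(
    ln_mean: np.ndarray, ln_var: np.ndarray, z_mode: str = "wald"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-gene inverse-variance meta-analysis.

    Returns (ADE, SE, Z) arrays over genes; genes with no contributing
    individual (all NaN) are NaN throughout.
    """
    ok = np.isfinite(ln_mean) & np.isfinite(ln_var) & (ln_var > 0)
    w = np.where(ok, 1.0 / np.where(ok, ln_var, 1.0), 0.0)
    wsum = w.sum(axis=1)
    any_ok = wsum > 0
    ade = np.full(ln_mean.shape[0], np.nan)
    se = np.full(ln_mean.shape[0], np.nan)
    num = (np.where(ok, ln_mean, 0.0) * w).sum(axis=1)
    ade[any_ok] = num[any_ok] / wsum[any_ok]
    se[any_ok] = np.sqrt(1.0 / wsum[any_ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = ade / se
    if z_mode == "ev_ratio":
        z = ade / np.square(se)
    return ade, se, z


def run_cocoa_stratum(
    counts: CellCountMatrix,
    meta: CellMeta,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, CocoaDecomposition]:
    """Run the full method on one (already stratified) count matrix."""
    emb = embed_spectral(
        counts, rank=config.rank, transform=config.transform, seed=config.seed
    )
    matches = match_opposite(emb, meta, k=config.knn, seed=config.seed)
    cf = impute_counterfactual(
        counts,
        matches,
        method=config.impute_method,
        k_use=config.k_use,
        ridge=config.ridge,
        tol=config.impute_tol,
    )
    dec = decompose(
        counts, cf, meta, max_iter=config.max_iter, tol=config.tol
    )
    _, _, inds = meta.cell_arrays(counts.cell_ids)
    is_case = np.array([meta.label_of[i] == 1 for i in inds])
    p = wilcoxon_matrix(dec.delta, is_case)
    finite_p = np.isfinite(p)
    q = np.full(p.shape, np.nan)
    q[finite_p] = adjust_multiplicity(p[finite_p], method=config.q_method)
    fwer = np.full(p.shape, np.nan)
    fwer[finite_p] = adjust_multiplicity(p[finite_p], method="holm")
    ade, se, z = ade_table(dec.ln_delta_mean, dec.ln_delta_var, z_mode=config.z_mode)
    table = pd.DataFrame(
        {
            "gene": counts.gene_ids,
            "n_case": int(is_case.sum()),
            "n_ctrl": int((~is_case).sum()),
            "wilcoxon_p": p,
            "q_value": q,
            "fwer_p": fwer,
            "ADE": ade,
            "SE": se,
            "Z": z,
        }
    )
    return table, dec


def run_cocoa_pipeline(
    counts: CellCountMatrix,
    meta: CellMeta,
    config: PipelineConfig | None = None,
    return_decompositions: bool = False,
):
    """Cell-type-stratified differential expression analysis.

    Returns a concatenated DEG table with a ``celltype`` column (one
    stratum named ``"all"`` when no annotation is present).  Strata with
    individuals of a single label are skipped with a logged warning.
    Output is a pure function of (inputs, config, seed).
    """
    if config is None:
        config = PipelineConfig()
    if meta.celltype_of is not None:
        groups: dict[str, list[int]] = {}
        for j, cid in enumerate(counts.cell_ids):
            groups.setdefault(meta.celltype_of[cid], []).append(j)
        strata = sorted(groups.items())
    else:
        strata = [("all", list(range(counts.n_cells)))]

    tables = []
    decs = {}
    for name, cell_idx in strata:
        sub = counts.subset_cells(np.array(cell_idx))
        labels = {meta.label_of[meta.individual_of[c]] for c in sub.cell_ids}
        if len(labels) < 2:
            msg = f"stratum {name!r} has individuals of only one label; skipped"
            logger.warning(msg)
            warnings.warn(msg)
            continue
        table, dec = run_cocoa_stratum(sub, meta, config)
        table.insert(1, "celltype", name)
        tables.append(table)
        decs[name] = dec
    if not tables:
        result = pd.DataFrame(
            columns=["gene", "celltype", "n_case", "n_ctrl",
                     "wilcoxon_p", "q_value", "fwer_p", "ADE", "SE", "Z"]
        )
    else:
        result = pd.concat(tables, ignore_index=True)
    if return_decompositions:
        return result, decs
    return result


def _row_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of a with the matching row of b."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    return num / np.maximum(den, 1e-300)


def evaluate_simulation(
    sim_config,
    pipeline_config: PipelineConfig | None = None,
    q_cutoff: float = 0.01,
) -> dict:
    """Simulate one cohort and score every pseudo-bulk method against truth.

    Runs the full confounder-adjusted pipeline plus the naive competitors
    (total, mean, Bayesian pseudo-bulk, and the confounder component
    itself), ranks genes per method by the rank-sum p-value, and returns
    AUPRC, the fraction of genes at BH q < cutoff, and empirical FDR for
    each, together with the confounder-recovery correlations:
    ``corr_confounder`` (per-gene correlation of ln μ̂ with the gene's true
    confounding predictor Σ_k X_ik β_kg, mean over non-causal genes),
    ``corr_label`` (same against the disease label, mean absolute), and
    ``corr_delta_unconfounded`` (pooled correlation of E[ln δ] with the
    true unconfounded log-mean over causal genes).
    """
    from .inference import auprc as _auprc
    from .inference import empirical_fdr
    from .pseudobulk import aggregate, fit_poisson_gamma_vb
    from .simulate import simulate_dataset

    if pipeline_config is None:
        pipeline_config = PipelineConfig(seed=sim_config.seed)
    counts, meta, truth = simulate_dataset(sim_config)
    _, dec = run_cocoa_stratum(counts, meta, pipeline_config)
    _, _, inds = meta.cell_arrays(counts.cell_ids)
    is_case = np.array([meta.label_of[i] == 1 for i in inds])

    bayes = fit_poisson_gamma_vb(counts, meta)
    matrices = {
        "cocoa": dec.delta,
        "confounder": dec.mu,
        "bayes": bayes.lambda_hat,
        "total": aggregate(counts, meta, "total").lambda_hat,
        "mean": aggregate(counts, meta, "mean").lambda_hat,
    }
    flags = truth.causal_flags
    out: dict = {"auprc": {}, "q_frac": {}, "efdr": {}, "p_values": {}}
    for name, mat in matrices.items():
        p = wilcoxon_matrix(mat, is_case)
        q = adjust_multiplicity(p, method="bh")
        out["p_values"][name] = p
        out["q_frac"][name] = float((q < q_cutoff).mean())
        out["efdr"][name] = empirical_fdr(q, flags, cutoff=q_cutoff)
        if 0 < flags.sum() < flags.size:
            out["auprc"][name] = _auprc(-p, flags)

    ln_mu = np.log(dec.mu)
    non_causal = ~flags
    c_conf = _row_corr(ln_mu[non_causal], truth.confound_effect[non_causal])
    w_rows = np.tile(truth.W.astype(float), (int(non_causal.sum()), 1))
    c_label = _row_corr(ln_mu[non_causal], w_rows)
    out["corr_confounder"] = float(c_conf.mean())
    out["corr_label"] = float(np.abs(c_label).mean())
    if flags.any():
        x = dec.ln_delta_mean[flags].ravel()
        y = truth.unconfounded_logmean[flags].ravel()
        ok = np.isfinite(x)
        out["corr_delta_unconfounded"] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return out


def run_manifest(config: PipelineConfig) -> dict:
    """Parameters and library versions, for the run log."""
    import scipy
    import sklearn

    import cocoadiff

    return {
        "config": asdict(config),
        "versions": {
            "cocoadiff": cocoadiff.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
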