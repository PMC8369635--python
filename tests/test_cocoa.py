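import numpy as np
import pytest
from scipy.special import psi
from scipy.stats import spearmanr

from cocoadiff.cocoa import decompose, estimate_confounder, estimate_residual
from cocoadiff.counterfactual import CounterfactualCounts, impute_counterfactual
from cocoadiff.matching import embed_spectral, match_opposite
from cocoadiff.pseudobulk import fit_poisson_gamma_vb

from conftest import make_counts, make_meta

EULER_GAMMA = 0.5772156649015329


def cohort_with_cf(rng, G=30, cells=(6, 6)):
    Y = rng.poisson(2.0, size=(G, sum(cells)))
    cm = make_counts(Y)
    cell_ind = np.repeat(np.arange(len(cells)), cells)
    meta = make_meta(cm.cell_ids, cell_ind, [0, 1][: len(cells)])
    return cm, meta, Y


def test_identical_counterfactual_satisfies_update(rng):
    # with Yhat = Y both condition halves are identical, so the fixed point
    # obeys E[mu] = (1 + 2*sum Y)/(1 + 2*sum E[rho]) with equal depths
    cm, meta, Y = cohort_with_cf(rng)
    cf = CounterfactualCounts(yhat=Y.astype(float), method="poisson_reg")
    mu, rho_w, inds, conv = estimate_confounder(cm, cf, meta, max_iter=5000, tol=1e-10)
    assert conv
    np.testing.assert_allclose(rho_w[0], rho_w[1], rtol=1e-8)
    cell_ind = np.array([0] * 6 + [1] * 6)
    for i in range(2):
        cells = cell_ind == i
        expect = (1 + 2 * Y[:, cells].sum(axis=1)) / (1 + 2 * rho_w[0][cells].sum())
        np.testing.assert_allclose(mu[:, i], expect, rtol=1e-6)


def test_confounder_invariant_to_relabeling(rng):
    cm, meta, Y = cohort_with_cf(rng)
    cf = CounterfactualCounts(yhat=rng.gamma(2.0, 1.0, size=Y.shape), method="poisson_reg")
    mu1, _, _, _ = estimate_confounder(cm, cf, meta, tol=1e-10)
    flipped = make_meta(cm.cell_ids, [0] * 6 + [1] * 6, [1, 0])
    mu2, _, _, _ = estimate_confounder(cm, cf, flipped, tol=1e-10)
    np.testing.assert_array_equal(mu1, mu2)


def test_confounder_matches_brute_force_oracle(rng):
    # oracle: the printed alternating recursion run 10x longer
    G, J = 50, 20
    Y = rng.poisson(1.5, size=(G, J))
    yhat = rng.gamma(1.5, 1.0, size=(G, J))
    cm = make_counts(Y)
    cell_ind = np.repeat(np.arange(4), 5)
    meta = make_meta(cm.cell_ids, cell_ind, [0, 1, 0, 1])
    cf = CounterfactualCounts(yhat=yhat, method="poisson_reg")
    mu, rho_w, _, _ = estimate_confounder(cm, cf, meta, max_iter=1000, tol=1e-9)

    rho_o = np.ones(J)
    rho_c = np.ones(J)
    for _ in range(10_000):
        mu_o = np.zeros((G, 4))
        for i in range(4):
            c = np.where(cell_ind == i)[0]
            num = 1 + Y[:, c].sum(axis=1) + yhat[:, c].sum(axis=1)
            den = 1 + rho_o[c].sum() + rho_c[c].sum()
            mu_o[:, i] = num / den
        for j in range(J):
            den = 1 + mu_o[:, cell_ind[j]].sum()
            rho_o[j] = (1 + Y[:, j].sum()) / den
            rho_c[j] = (1 + yhat[:, j].sum()) / den
    assert np.max(np.abs(mu - mu_o) / mu_o) < 1e-6
    assert np.max(np.abs(rho_w[0] - rho_o) / rho_o) < 1e-6


def test_unit_confounder_reduces_to_bayes_pseudobulk(rng):
    cm, meta, Y = cohort_with_cf(rng)
    mu = np.ones((30, 2))
    delta, _, _, rho, _ = estimate_residual(cm, mu, meta, tol=1e-10)
    pb = fit_poisson_gamma_vb(cm, meta, tol=1e-10)
    np.testing.assert_allclose(delta, pb.lambda_hat, rtol=1e-6)
    np.testing.assert_allclose(rho, pb.rho_hat, rtol=1e-6)


def test_ln_delta_closed_forms():
    # single gene, single cell, Y=1, mu=1: fixed point delta=rho=1 so
    # E[ln delta] = psi(2) - ln 2 = (1 - gamma) - ln 2, V[ln delta] = 1
    cm = make_counts([[1]])
    meta = make_meta(cm.cell_ids, [0], [1])
    delta, ln_mean, ln_var, rho, _ = estimate_residual(cm, np.ones((1, 1)), meta, tol=1e-12)
    assert delta[0, 0] == pytest.approx(1.0, abs=1e-8)
    assert ln_mean[0, 0] == pytest.approx((1 - EULER_GAMMA) - np.log(2), abs=1e-6)
    assert ln_var[0, 0] == pytest.approx(1.0)
    assert ln_mean[0, 0] == pytest.approx(psi(2) - np.log(2), abs=1e-6)


def test_ln_delta_variance_reciprocal_counts():
    cm = make_counts([[4]])
    meta = make_meta(cm.cell_ids, [0], [1])
    _, _, ln_var, _, _ = estimate_residual(cm, np.ones((1, 1)), meta)
    assert ln_var[0, 0] == pytest.approx(0.25)


def test_zero_count_pairs_marked_missing(rng):
    Y = rng.poisson(2.0, size=(5, 8))
    Y[3] = 0
    cm = make_counts(Y)
    meta = make_meta(cm.cell_ids, [0] * 4 + [1] * 4, [0, 1])
    delta, ln_mean, ln_var, _, _ = estimate_residual(cm, np.ones((5, 2)), meta)
    assert np.all(np.isfinite(delta))
    assert np.isnan(ln_mean[3]).all() and np.isnan(ln_var[3]).all()
    assert np.isfinite(ln_mean[0]).all()


def test_nonpositive_mu_rejected(rng):
    cm, meta, _ = cohort_with_cf(rng, G=3)
    with pytest.raises(ValueError, match="positive"):
        estimate_residual(cm, np.zeros((3, 2)), meta)


def test_reconstruction_tracks_bayes_pseudobulk(small_cohort):
    counts, meta, _ = small_cohort
    emb = embed_spectral(counts, rank=10, seed=0)
    ms = match_opposite(emb, meta, k=10)
    cf = impute_counterfactual(counts, ms)
    dec = decompose(counts, cf, meta)
    lam = fit_poisson_gamma_vb(counts, meta).lambda_hat
    r, _ = spearmanr((dec.mu * dec.delta).ravel(), lam.ravel())
    assert r > 0.99


def test_decomposition_export_round_trip(small_cohort, tmp_path):
    counts, meta, _ = small_cohort
    emb = embed_spectral(counts, rank=10, seed=0)
    ms = match_opposite(emb, meta, k=10)
    cf = impute_counterfactual(counts, ms)
    dec = decompose(counts, cf, meta)
    df = dec.to_frame()
    assert len(df) == counts.n_genes * len(dec.individual_ids)
    df.to_csv(tmp_path / "decomposition.tsv", sep="\t", index=False)
    import pandas as pd

    back = pd.read_csv(tmp_path / "decomposition.tsv", sep="\t")
    np.testing.assert_allclose(
        back["mu"].to_numpy().reshape(dec.mu.shape), dec.mu, rtol=1e-12
    )


def test_delta_correlates_with_unconfounded_truth():
    from cocoadiff.pipeline import PipelineConfig, evaluate_simulation
    from cocoadiff.simulate import SimConfig

    cfg = SimConfig(
        n_genes=1000, n_causal=50, n_individuals=40, cells_per_individual=30,
        var_xw=0.5, var_wy=0.3, var_xby=0.5, d_confounders=5, seed=11,
    )
    res = evaluate_simulation(cfg, PipelineConfig(rank=20, knn=20, seed=11))
    assert res["corr_delta_unconfounded"] > 0.5
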