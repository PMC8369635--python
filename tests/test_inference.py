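import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import polygamma, psi

from cocoadiff.inference import (
    ade_se,
    adjust_multiplicity,
    auprc,
    empirical_fdr,
    gamma_log_gaussian,
    meta_average,
    storey_qvalues,
    wilcoxon_matrix,
    wilcoxon_ranksum,
)


def exact_ranksum_oracle(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    obs = ranks[:n1].sum()
    stats = [
        sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)
    ]
    stats = np.array(stats)
    mean = stats.mean()
    lo = (stats <= obs).mean()
    hi = (stats >= obs).mean()
    return min(1.0, 2 * min(lo, hi))


@pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 7) for n2 in range(1, 7)])
def test_wilcoxon_exact_matches_enumeration(n1, n2):
    rng = np.random.default_rng(100 * n1 + n2)
    x = rng.normal(size=n1)
    y = rng.normal(size=n2)
    assert wilcoxon_ranksum(x, y) == pytest.approx(exact_ranksum_oracle(x, y), abs=1e-12)


def test_wilcoxon_separated_groups():
    # 2 of the 20 equally likely assignments are as extreme
    assert wilcoxon_ranksum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_wilcoxon_identical_groups_tie_corrected():
    assert wilcoxon_ranksum([1, 2], [1, 2]) == pytest.approx(1.0)


def test_wilcoxon_symmetry(rng):
    x = rng.normal(size=8)
    y = rng.normal(size=11)
    assert wilcoxon_ranksum(x, y) == pytest.approx(wilcoxon_ranksum(y, x))


def test_wilcoxon_missing_and_empty(rng):
    assert np.isnan(wilcoxon_ranksum([], [1.0, 2.0]))
    x = np.array([1.0, np.nan, 2.0])
    assert wilcoxon_ranksum(x, [3.0, 4.0]) == pytest.approx(
        wilcoxon_ranksum([1.0, 2.0], [3.0, 4.0])
    )


def test_wilcoxon_matrix_consistent_with_scalar(rng):
    vals = rng.normal(size=(5, 20))
    is_case = np.arange(20) < 9
    p = wilcoxon_matrix(vals, is_case)
    for g in range(5):
        assert p[g] == pytest.approx(
            wilcoxon_ranksum(vals[g, is_case], vals[g, ~is_case])
        )


def test_gamma_log_gaussian_branches():
    a = gamma_log_gaussian(2.0, 1.0)
    assert (a.mean, a.var) == (pytest.approx(0.0), pytest.approx(1.0))
    b = gamma_log_gaussian(1.0, 2.0)
    assert (b.mean, b.var) == (pytest.approx(np.log(0.5)), pytest.approx(1.0))
    with pytest.raises(ValueError):
        gamma_log_gaussian(0.0, 1.0)


def test_gamma_log_gaussian_against_monte_carlo(rng):
    # exact moments of ln Gamma(a,b) are psi(a)-ln b and trigamma(a);
    # Monte Carlo stands in as the independent route
    draws = np.log(rng.gamma(100.0, 1.0, size=1_000_000))
    approx = gamma_log_gaussian(100.0, 1.0)
    assert approx.mean == pytest.approx(draws.mean(), rel=0.02)
    assert approx.var == pytest.approx(draws.var(), rel=0.02)
    assert approx.mean == pytest.approx(psi(100.0), rel=0.005)
    assert approx.var == pytest.approx(polygamma(1, 100.0), rel=0.02)


def test_meta_average_closed_form():
    assert meta_average([1, 3], [1, 1]) == (pytest.approx(2.0), pytest.approx(0.5))
    assert meta_average([0.7], [0.09]) == (pytest.approx(0.7), pytest.approx(0.09))
    eta, var = meta_average([0, 10], [1, 1e6])
    assert eta == pytest.approx(10 / (1 + 1e-6) * 1e-6, rel=1e-3)
    assert eta < 1e-4


def test_meta_average_properties(rng):
    etas = rng.normal(size=7)
    vars_ = rng.gamma(2.0, 1.0, size=7) + 0.05
    e1, v1 = meta_average(etas, vars_)
    perm = rng.permutation(7)
    e2, v2 = meta_average(etas[perm], vars_[perm])
    assert e1 == pytest.approx(e2) and v1 == pytest.approx(v2)
    assert v1 <= vars_.min()
    # independent recomputation of the printed sums
    w = 1 / vars_
    assert e1 == pytest.approx((etas * w).sum() / w.sum())
    with pytest.raises(ValueError):
        meta_average([], [])


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(-5, 5, allow_nan=False),
            st.floats(0.01, 10, allow_nan=False),
        ),
        min_size=1,
        max_size=20,
    )
)
def test_meta_average_pooling_properties(pairs):
    # pooled estimate stays inside the convex hull; pooling never loses precision
    etas = np.array([e for e, _ in pairs])
    vars_ = np.array([v for _, v in pairs])
    eta_bar, var_bar = meta_average(etas, vars_)
    assert var_bar <= vars_.min() + 1e-12
    assert etas.min() - 1e-9 <= eta_bar <= etas.max() + 1e-9


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(0, 10_000), st.integers(5, 60))
def test_auprc_within_unit_interval_above_prevalence_floor(seed, n):
    rng = np.random.default_rng(seed)
    flags = rng.random(n) < 0.4
    if flags.all() or not flags.any():
        flags[0] = True
        flags[1] = False
    scores = rng.normal(size=n)
    val = auprc(scores, flags)
    assert 0.0 < val <= 1.0
    # a ranking can never average below the worst-case single-point floor
    assert val >= flags.sum() / (2.0 * n)


def test_ade_se_single_individual():
    ade, se, z = ade_se(np.array([0.5]), np.array([0.25]))
    assert (ade, se) == (pytest.approx(0.5), pytest.approx(0.5))
    assert z[0] == pytest.approx(1.0)


def test_ade_zero_effects():
    ade, se, _ = ade_se(np.zeros(5), np.linspace(0.1, 2, 5))
    assert ade == pytest.approx(0.0)


def test_ade_se_missing_handling():
    eta = np.array([0.5, np.nan, 1.0])
    var = np.array([0.25, np.nan, 1.0])
    ade, se, z = ade_se(eta, var)
    e_ref, v_ref = meta_average([0.5, 1.0], [0.25, 1.0])
    assert ade == pytest.approx(e_ref) and se == pytest.approx(np.sqrt(v_ref))
    assert np.isnan(z[1])
    ade2, se2, _ = ade_se(np.array([np.nan]), np.array([np.nan]))
    assert np.isnan(ade2) and np.isnan(se2)


def test_ade_z_modes():
    _, _, z_wald = ade_se(np.array([0.8]), np.array([0.16]), z_mode="wald")
    _, _, z_ev = ade_se(np.array([0.8]), np.array([0.16]), z_mode="ev_ratio")
    assert z_wald[0] == pytest.approx(0.8 / 0.4)
    assert z_ev[0] == pytest.approx(0.8 / 0.16)


def test_bh_step_up():
    np.testing.assert_allclose(
        adjust_multiplicity([0.01, 0.02, 0.03], "bh"), [0.03, 0.03, 0.03]
    )


@pytest.mark.parametrize("method", ["bh", "storey_q", "bonferroni", "holm"])
def test_all_unit_pvalues_stay_unit(method):
    np.testing.assert_allclose(adjust_multiplicity(np.ones(10), method), 1.0)


def test_storey_below_bh(rng):
    p = rng.uniform(size=200) ** 2
    q = storey_qvalues(p)
    bh = adjust_multiplicity(p, "bh")
    assert np.all(q <= bh + 1e-12)


def test_invalid_pvalues_rejected():
    with pytest.raises(ValueError):
        adjust_multiplicity([0.0, 0.5], "bh")
    with pytest.raises(ValueError):
        adjust_multiplicity([0.5], "unknown_method")


def brute_force_auprc(scores, flags):
    """Point-by-point PR curve with tie grouping, trapezoid area."""
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    pts = []
    for t in sorted(set(scores), reverse=True):
        sel = scores >= t
        pts.append((flags[sel].sum() / flags.sum(), flags[sel].mean()))
    recall = [0.0] + [r for r, _ in pts]
    prec = [pts[0][1]] + [p for _, p in pts]
    return np.trapezoid(prec, recall)


def test_auprc_perfect_ranking():
    flags = np.array([1, 1, 0, 0, 0], dtype=bool)
    assert auprc([5, 4, 3, 2, 1], flags) == pytest.approx(1.0)


def test_auprc_matches_brute_force(rng):
    for _ in range(20):
        n = rng.integers(5, 50)
        scores = np.round(rng.normal(size=n), 1)  # provoke ties
        flags = rng.random(n) < 0.3
        if flags.all() or not flags.any():
            continue
        assert auprc(scores, flags) == pytest.approx(brute_force_auprc(scores, flags))


def test_auprc_random_scores_near_prevalence(rng):
    vals = [
        auprc(rng.normal(size=10_000), np.arange(10_000) < 50) for _ in range(100)
    ]
    assert np.mean(vals) == pytest.approx(0.005, abs=0.002)


def test_auprc_single_class_rejected():
    with pytest.raises(ValueError):
        auprc([1.0, 2.0], [True, True])


def test_empirical_fdr():
    q = np.array([0.001] * 10 + [0.5] * 5)
    flags = np.array([True] * 8 + [False] * 7)
    assert empirical_fdr(q, flags) == pytest.approx(0.2)
    assert empirical_fdr(np.ones(5), flags[:5]) == 0.0
    assert empirical_fdr(np.zeros(3), np.zeros(3, dtype=bool)) == 1.0
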