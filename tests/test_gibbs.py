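import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ldpgs
from ldpgs import (
    GibbsState,
    HyperParams,
    LDpredGibbs,
    ScaledBetas,
    causal_posterior_prob,
    default_grid,
    gibbs_sweep,
    residualized_effect,
    run_gibbs,
    run_grid,
    solve_inf,
)
from ldpgs.ld import LDMatrix
from ldpgs.simulate import simulate_sumstats_model


def _ld_from_dense(R, window_cM=np.inf):
    import scipy.sparse as sp

    m = R.shape[0]
    return LDMatrix(
        R=sp.csr_matrix(R),
        genpos=np.zeros(m),
        variants=pd.DataFrame({"chr": "1", "pos": np.arange(m) + 1, "a0": "A", "a1": "C"}),
        window_cM=window_cM,
    )


def _scaled(beta_hat, n):
    beta_hat = np.asarray(beta_hat, float)
    return ScaledBetas(
        beta_hat=beta_hat, scale=np.ones_like(beta_hat), n=np.full(beta_hat.size, float(n))
    )


def _naive_causal_prob(btilde, p, h2, n, M):
    """Unsimplified two-Gaussian-density form of the causal probability,
    evaluated in extended precision."""
    ld_ = np.longdouble
    btilde, p, h2, n = ld_(btilde), ld_(p), ld_(h2), ld_(n)
    v1 = h2 / (ld_(M) * p) + 1 / n
    v0 = 1 / n
    num = p / np.sqrt(v1) * np.exp(-btilde**2 / (2 * v1))
    den = num + (1 - p) / np.sqrt(v0) * np.exp(-btilde**2 / (2 * v0))
    with np.errstate(invalid="ignore"):
        return float(num / den)


class TestCausalPosteriorProb:
    def test_p_one_is_certain(self):
        assert causal_posterior_prob(5.0, 1.0, 0.5, 1000, 100) == 1.0

    def test_btilde_zero_ratio_case(self):
        # n h2/(M p) = 3 -> pbar = 1/(1+sqrt(4)) = 1/3
        assert causal_posterior_prob(0.0, 0.5, 1.0, 600, 400) == pytest.approx(1 / 3)

    def test_huge_signal_no_overflow(self):
        # n btilde^2 = 1e6 at p = 1e-5: must stay finite and hit ~1
        with np.errstate(over="raise"):
            pbar = causal_posterior_prob(np.sqrt(1e6 / 2e4), 1e-5, 0.3, 2e4, 1000)
        assert 1 - pbar < 1e-15
        oracle = _naive_causal_prob(np.sqrt(1e6 / 2e4), 1e-5, 0.3, 2e4, 1000)
        assert pbar == pytest.approx(oracle, abs=1e-12)

    @settings(deadline=None, max_examples=300)
    @given(
        st.floats(-2, 2),
        st.floats(1e-5, 1),
        st.floats(0.01, 1),
        st.floats(100, 1e6),
        st.integers(10, 100000),
    )
    def test_stable_matches_naive_form(self, btilde, p, h2, n, M):
        naive = _naive_causal_prob(btilde, p, h2, n, M)
        if np.isfinite(naive):
            assert causal_posterior_prob(btilde, p, h2, n, M) == pytest.approx(
                naive, abs=1e-12
            )

    def test_constant_n_vector_matches_scalar(self):
        # per-variant n_j plumbing: equal n_j reproduces the scalar-n value
        b = np.array([0.01, -0.02, 0.3])
        vec = causal_posterior_prob(b, 0.1, 0.4, np.full(3, 5000.0), 1000)
        scal = [causal_posterior_prob(x, 0.1, 0.4, 5000.0, 1000) for x in b]
        np.testing.assert_allclose(vec, scal, rtol=0, atol=0)

    def test_omega_vanishes_as_p_to_zero_for_weak_signals(self):
        # |omega| = pbar * shrink * |btilde| -> 0 in the p -> 0 limit; for
        # weak evidence (|Z| <= 5) the collapse is already near-complete at
        # p = 1e-12 (for very strong signals it occurs only at untestably
        # small p because the likelihood ratio overwhelms the prior odds)
        rng = np.random.default_rng(0)
        for _ in range(50):
            h2, n, M = rng.uniform(0.05, 0.8), rng.uniform(1e3, 1e5), 1000
            btilde = rng.uniform(-5, 5) / np.sqrt(n)
            def om(p):
                return abs(causal_posterior_prob(btilde, p, h2, n, M) * btilde
                           / (1 + M * p / (n * h2)))
            assert om(1e-12) <= 1e-3 * om(1.0) + 1e-300


class TestResidualizedEffect:
    def test_identity_R_and_zero_beta(self):
        beta = np.zeros(3)
        rbeta = np.zeros(3)
        assert residualized_effect(1, 0.2, beta, rbeta) == pytest.approx(0.2)
        beta = np.array([0.1, 0.2, 0.3])
        rbeta = beta.copy()  # identity R
        assert residualized_effect(1, 0.5, beta, rbeta) == pytest.approx(0.5)

    def test_two_variant_hand_case(self):
        # r = 0.5, beta_hat = (0.1, 0.2), beta = (0.05, 0.1)
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        beta = np.array([0.05, 0.1])
        rbeta = R @ beta
        assert residualized_effect(0, 0.1, beta, rbeta) == pytest.approx(0.1 - 0.5 * 0.1)


class TestSolveInf:
    def test_identity_diagonal_system(self):
        ld = _ld_from_dense(np.eye(2))
        sb = _scaled([0.3, -0.1], 100)
        # M/(n h2) = 2/(100*0.5) = 0.04
        np.testing.assert_allclose(solve_inf(sb, ld, 0.5), np.array([0.3, -0.1]) / 1.04)

    def test_dense_direct_solve_oracle(self, rng):
        m = 20
        A = rng.standard_normal((m, 3 * m))
        R = np.corrcoef(A)
        ld = _ld_from_dense(R)
        sb = _scaled(rng.normal(0, 0.05, m), 20000)
        x = solve_inf(sb, ld, 0.4)
        expect = np.linalg.solve(R + (m / (20000 * 0.4)) * np.eye(m), sb.beta_hat)
        np.testing.assert_allclose(x, expect, atol=1e-8)

    def test_h2_infinity_gives_joint_effects(self, rng):
        m = 5
        A = rng.standard_normal((m, 50))
        R = np.corrcoef(A)
        sb = _scaled(rng.normal(0, 0.05, m), 1000)
        x = solve_inf(sb, _ld_from_dense(R), 1e12)
        np.testing.assert_allclose(x, np.linalg.solve(R, sb.beta_hat), atol=1e-6)


def _single_variant_closed_form(gamma, se, n, p, h2):
    """Posterior mean computed by hand for M=1 (btilde = beta_hat always)."""
    beta_hat = gamma / (se * np.sqrt(n))
    shrink = 1 / (1 + p / (n * h2))
    pbar = causal_posterior_prob(beta_hat, p, h2, n, 1)
    return pbar * shrink * beta_hat * se * np.sqrt(n)  # back-scaled


class TestRunGibbs:
    def test_single_variant_exact(self):
        gamma, se, n = 0.03, 0.01, 5000.0
        ss = pd.DataFrame(
            {"chr": ["1"], "pos": [1], "a0": ["A"], "a1": ["C"],
             "gamma_hat": [gamma], "se_gamma": [se], "n": [n]}
        )
        sb = ldpgs.scale_to_std(ss)
        hp = HyperParams(p=0.3, h2=0.2)
        res = run_gibbs(sb, _ld_from_dense(np.eye(1)), hp, burn_in=10, num_iter=50, seed=0)
        expect = _single_variant_closed_form(gamma, se, n, 0.3, 0.2)
        assert sb.back_scale(res.omega)[0] == pytest.approx(expect, abs=1e-14)
        assert res.effects[0] == pytest.approx(expect, abs=1e-14)

    def test_same_seed_bit_identical(self):
        scaled, _, ld = simulate_sumstats_model(m=100, n=5000, p=0.1, seed=2)
        hp = HyperParams(p=0.1, h2=0.3)
        r1 = run_gibbs(scaled, ld, hp, 20, 50, seed=7)
        r2 = run_gibbs(scaled, ld, hp, 20, 50, seed=7)
        np.testing.assert_array_equal(r1.omega, r2.omega)

    def test_sparse_zero_input_gives_zero_output(self):
        sb = _scaled(np.zeros(20), 1000)
        ld = _ld_from_dense(np.eye(20))
        res = run_gibbs(sb, ld, HyperParams(p=0.01, h2=0.3, sparse=True), 10, 50, seed=1)
        np.testing.assert_array_equal(res.omega, 0.0)
        assert res.sparsity == 1.0

    def test_incremental_cache_matches_full_recompute(self):
        scaled, _, ld = simulate_sumstats_model(m=50, n=5000, p=0.2, seed=4)
        kwargs = dict(p=0.2, h2=0.3, burn_in=50, num_iter=200, random_state=3)
        inc = LDpredGibbs(refresh_every=10**9, **kwargs).fit(scaled, ld)
        full = LDpredGibbs(refresh_every=1, **kwargs).fit(scaled, ld)
        np.testing.assert_allclose(inc.omega_, full.omega_, atol=1e-10)

    def test_matches_python_reference_sweep_single_variant(self):
        # kernel vs the pure-Python reference path where both are deterministic
        sb = _scaled([0.02], 1000)
        ld = _ld_from_dense(np.eye(1))
        hp = HyperParams(p=0.5, h2=0.1)
        state = GibbsState.init(1, hp, seed=0)
        om = gibbs_sweep(state, sb, ld, hp)
        res = run_gibbs(sb, ld, hp, burn_in=0, num_iter=1, seed=0)
        np.testing.assert_allclose(om, res.omega, atol=1e-14)

    def test_sparse_has_exact_zeros_nonsparse_none(self):
        scaled, _, ld = simulate_sumstats_model(m=200, n=20000, p=0.05, seed=5)
        sp_res = run_gibbs(scaled, ld, HyperParams(0.05, 0.3, sparse=True), 50, 100, seed=0)
        ns_res = run_gibbs(scaled, ld, HyperParams(0.05, 0.3, sparse=False), 50, 100, seed=0)
        assert np.any(sp_res.omega == 0.0)
        assert not np.any(ns_res.omega == 0.0)

    def test_infinitesimal_equivalence_at_p_one(self):
        scaled, _, ld = simulate_sumstats_model(m=10, n=5000, p=1.0, h2=0.4, rho=0.3, seed=3)
        x = solve_inf(scaled, ld, 0.4)
        oms = np.array(
            [run_gibbs(scaled, ld, HyperParams(1.0, 0.4), 200, 2000, seed=s).omega
             for s in range(8)]
        )
        se = oms.std(axis=0, ddof=1) / np.sqrt(oms.shape[0])
        assert np.all(np.abs(oms.mean(axis=0) - x) <= 3 * se)


class TestDefaultGrid:
    def test_grid_size_126(self):
        assert len(default_grid(0.2)) == 126

    def test_endpoints_and_log_spacing(self):
        grid = default_grid(0.5)
        ps = sorted({hp.p for hp in grid})
        assert ps[0] == pytest.approx(1e-5, rel=1e-12)
        assert ps[-1] == 1.0
        ratios = np.diff(np.log(ps))
        np.testing.assert_allclose(ratios, ratios[0], atol=1e-12)
        assert {round(hp.h2 / 0.5, 10) for hp in grid} == {0.7, 1.0, 1.4}
        assert {hp.sparse for hp in grid} == {False, True}


class TestRunGrid:
    def test_size_one_reduces_to_run_gibbs(self):
        scaled, _, ld = simulate_sumstats_model(m=50, n=5000, p=0.1, seed=6)
        hp = HyperParams(0.1, 0.3)
        grid_res = run_grid(scaled, ld, [hp], 20, 50, seed=9)
        single = run_gibbs(scaled, ld, hp, 20, 50, seed=9)
        np.testing.assert_array_equal(grid_res[0].omega, single.omega)

    def test_thread_count_invariance(self):
        scaled, _, ld = simulate_sumstats_model(m=30, n=5000, p=0.2, seed=7)
        grid = [HyperParams(p, 0.3) for p in (0.01, 0.1, 1.0)]
        r1 = run_grid(scaled, ld, grid, 20, 50, seed=1, threads=1)
        r4 = run_grid(scaled, ld, grid, 20, 50, seed=1, threads=4)
        for a, b in zip(r1, r4):
            np.testing.assert_array_equal(a.omega, b.omega)
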