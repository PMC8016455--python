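import numpy as np
import pytest

from ldpgs import (
    HyperParams,
    LDpredAuto,
    auto_init_p,
    auto_sparse,
    combine_chains,
    estimate_h2_from_beta,
    run_auto_chain,
    run_gibbs,
    sample_p_posterior,
)
from ldpgs.models import AutoChain
from ldpgs.simulate import simulate_sumstats_model


class TestSamplePPosterior:
    def test_beta_mean_no_causals(self, rng):
        draws = [sample_p_posterior(0, 100, rng) for _ in range(100_000)]
        mean, se = np.mean(draws), np.std(draws) / np.sqrt(len(draws))
        assert abs(mean - 1 / 102) <= 3 * se

    def test_symmetry_all_causal(self, rng):
        d0 = [sample_p_posterior(0, 100, rng) for _ in range(50_000)]
        d1 = [sample_p_posterior(100, 100, rng) for _ in range(50_000)]
        assert np.mean(d1) + np.mean(d0) == pytest.approx(1.0, abs=0.005)

    def test_balanced_moments(self, rng):
        d = np.array([sample_p_posterior(50, 100, rng) for _ in range(100_000)])
        # Beta(51, 51): mean 1/2, var = 51*51/(102^2 * 103)
        var = 51 * 51 / (102**2 * 103)
        assert d.mean() == pytest.approx(0.5, abs=3 * np.sqrt(var / len(d)))
        assert d.var() == pytest.approx(var, rel=0.05)

    def test_bounds(self, rng):
        with pytest.raises(ValueError):
            sample_p_posterior(-1, 10, rng)


class TestEstimateH2:
    def test_zero_beta_floored_and_flagged(self):
        _, _, ld = simulate_sumstats_model(m=30, n=1000, seed=0)
        h2, floored = estimate_h2_from_beta(np.zeros(30), ld)
        assert h2 == 1e-4 and floored

    def test_identity_R_sum_of_squares(self):
        import pandas as pd
        import scipy.sparse as sp

        from ldpgs.ld import LDMatrix

        beta = np.array([0.1, -0.2, 0.3])
        ld = LDMatrix(
            R=sp.eye(3, format="csr"), genpos=np.zeros(3),
            variants=pd.DataFrame({"chr": "1", "pos": [1, 2, 3], "a0": "A", "a1": "C"}),
            window_cM=3.0,
        )
        h2, floored = estimate_h2_from_beta(beta, ld)
        assert h2 == pytest.approx(np.sum(beta**2)) and not floored

    def test_dense_quadratic_form_oracle(self, rng):
        _, _, ld = simulate_sumstats_model(m=30, n=1000, seed=1)
        beta = rng.normal(0, 0.1, 30)
        h2, _ = estimate_h2_from_beta(beta, ld)
        assert h2 == pytest.approx(beta @ ld.R.toarray() @ beta, abs=1e-12)


class TestRunAutoChain:
    def test_determinism(self):
        scaled, _, ld = simulate_sumstats_model(m=100, n=10000, p=0.05, seed=2)
        c1 = run_auto_chain(scaled, ld, 0.1, 0.3, burn_in=20, num_iter=50, seed=5)
        c2 = run_auto_chain(scaled, ld, 0.1, 0.3, burn_in=20, num_iter=50, seed=5)
        np.testing.assert_array_equal(c1.p_traj, c2.p_traj)
        np.testing.assert_array_equal(c1.omega, c2.omega)

    def test_updates_disabled_reproduces_fixed_sampler(self):
        scaled, _, ld = simulate_sumstats_model(m=80, n=10000, p=0.05, seed=3)
        chain = run_auto_chain(
            scaled, ld, 0.1, 0.3, burn_in=20, num_iter=50, seed=4, update_hyper=False
        )
        fixed = run_gibbs(scaled, ld, HyperParams(0.1, 0.3), 20, 50, seed=4)
        np.testing.assert_array_equal(chain.omega, fixed.omega)
        assert np.all(chain.p_traj == 0.1) and np.all(chain.h2_traj == 0.3)

    def test_null_data_h2_near_zero(self):
        rng = np.random.default_rng(6)
        from ldpgs import ScaledBetas
        from test_gibbs import _ld_from_dense

        m, n = 500, 50000
        sb = ScaledBetas(
            beta_hat=rng.standard_normal(m) / np.sqrt(n),
            scale=np.ones(m), n=np.full(m, float(n)),
        )
        chain = run_auto_chain(sb, _ld_from_dense(np.eye(m)), 0.1, 0.1, 100, 200, seed=7)
        assert chain.diverged or chain.h2_hat <= 0.02

    def test_trajectory_lengths(self):
        scaled, _, ld = simulate_sumstats_model(m=50, n=10000, seed=8)
        chain = run_auto_chain(scaled, ld, 0.2, 0.3, burn_in=10, num_iter=30, seed=9)
        assert len(chain.p_traj) == 40 == len(chain.h2_traj)
        assert np.all((chain.p_traj > 0) & (chain.p_traj < 1))
        assert np.all(np.isfinite(chain.h2_traj))


def _const_chain(omega, init_p=0.1):
    m = omega.size
    return AutoChain(
        init_p=init_p, init_h2=0.3, p_traj=np.full(5, 0.1), h2_traj=np.full(5, 0.3),
        beta=omega.copy(), omega=omega.copy(), p_hat=0.1, h2_hat=0.3, diverged=False,
    )


class TestCombineChains:
    @staticmethod
    def _fixture(m=30, seed=0):
        scaled, _, ld = simulate_sumstats_model(m=m, n=1000, seed=seed)
        return scaled, ld

    def test_identical_chains_all_kept(self):
        scaled, ld = self._fixture()
        chains = [_const_chain(np.full(30, 0.01)) for _ in range(5)]
        res, kept = combine_chains(chains, scaled, ld)
        assert kept == [0, 1, 2, 3, 4]
        np.testing.assert_allclose(res.omega, chains[0].omega)

    def test_outlier_excluded_by_mad(self):
        scaled, ld = self._fixture()
        rng = np.random.default_rng(1)
        chains = [_const_chain(0.01 + rng.normal(0, 1e-4, 30)) for _ in range(29)]
        chains.append(_const_chain(np.full(30, 5.0)))  # SD ~ 100x the rest
        _, kept = combine_chains(chains, scaled, ld)
        # the gross outlier must go; nearly all inliers stay (3 MADs ~ 2 sigma)
        assert 29 not in kept and len(kept) >= 27

    def test_mad_filter_scale_equivariant(self):
        scaled, ld = self._fixture()
        rng = np.random.default_rng(2)
        base = [0.01 + rng.normal(0, 2e-3, 30) for _ in range(10)]
        chains_a = [_const_chain(b) for b in base]
        chains_b = [_const_chain(7.0 * b) for b in base]
        _, kept_a = combine_chains(chains_a, scaled, ld)
        _, kept_b = combine_chains(chains_b, scaled, ld)
        assert kept_a == kept_b

    def test_diverged_chains_never_used(self):
        scaled, ld = self._fixture()
        good = _const_chain(np.full(30, 0.01))
        bad = _const_chain(np.full(30, 99.0))
        bad.diverged = True
        res, kept = combine_chains([good, bad], scaled, ld)
        assert kept == [0]
        with pytest.raises(ValueError, match="diverged"):
            combine_chains([bad], scaled, ld)

    def test_predictor_sd_from_panel(self):
        from conftest import make_panel

        scaled, ld = self._fixture()
        panel = make_panel(n=50, m=30, seed=3)
        panel.variants[["chr", "pos", "a0", "a1"]] = ld.variants[
            ["chr", "pos", "a0", "a1"]
        ].values
        chains = [_const_chain(np.full(30, 0.01)) for _ in range(3)]
        res, kept = combine_chains(chains, scaled, ld, ref_panel=panel)
        assert len(kept) == 3
        assert np.isfinite(chains[0].predictor_sd) and chains[0].predictor_sd > 0


def test_auto_init_grid_endpoints():
    inits = auto_init_p(30)
    assert len(inits) == 30
    assert inits[0] == pytest.approx(1e-4, rel=1e-12)
    assert inits[-1] == pytest.approx(0.9, rel=1e-12)
    np.testing.assert_allclose(np.diff(np.log(inits)), np.diff(np.log(inits))[0])


class TestAutoRecovery:
    def test_p_hat_tracks_polygenicity(self):
        # more causal variants -> larger p_hat, at fixed h2
        for seed in range(3):
            p_hats = []
            for p_true in (0.001, 0.01, 0.1):
                scaled, _, ld = simulate_sumstats_model(
                    m=2000, n=20000, p=p_true, h2=0.3, seed=seed
                )
                est = LDpredAuto(n_chains=6, burn_in=200, num_iter=200,
                                 random_state=seed).fit(scaled, ld)
                p_hats.append(est.p_hat_)
            assert p_hats[0] < p_hats[1] < p_hats[2]

    def test_auto_sparse_matches_nonsparse(self):
        scaled, _, ld = simulate_sumstats_model(m=500, n=20000, p=0.05, h2=0.3, seed=11)
        est = LDpredAuto(n_chains=4, burn_in=200, num_iter=300, random_state=1).fit(scaled, ld)
        sp_res = auto_sparse(scaled, ld, est.p_hat_, est.h2_hat_, 200, 300, seed=2)
        assert np.any(sp_res.omega == 0.0)
        assert sp_res.sparsity > 0
        r = np.corrcoef(sp_res.omega, est.omega_)[0, 1]
        assert r > 0.95

    def test_sparse_at_p_one_forces_no_zeros(self):
        scaled, _, ld = simulate_sumstats_model(m=100, n=20000, p=0.5, h2=0.3, seed=12)
        res = auto_sparse(scaled, ld, 1.0, 0.3, 50, 100, seed=3)
        assert res.sparsity == 0.0
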