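"""Functional surface over the auto model (hyper-parameter-free sampler).

The auto model treats the causal proportion p and the SNP heritability h2
as unknowns updated between Gibbs sweeps: p from its Beta posterior given
the count of currently nonzero effects, h2 from the quadratic form
beta' R beta.  Many chains are started from dispersed initial p values and
combined after a MAD filter on predictor standard deviations.
"""

from __future__ import annotations

import numpy as np

from .io import GenotypePanel
from .ld import LDMatrix
from .models import (  # noqa: F401  (re-exported surface)
    AutoChain,
    HyperParams,
    LDpredAuto,
    LDpredGibbs,
    PgsResult,
    _chain_seed,
    auto_init_p,
    combine_chains,
)
from .prep import ScaledBetas


def sample_p_posterior(mc: int, M: int, rng: np.random.Generator) -> float:
    """One draw of p from Beta(1 + Mc, 1 + M - Mc) (uniform prior)."""
    if not 0 <= mc <= M:
        raise ValueError("causal count must be between 0 and M")
    return float(rng.beta(1.0 + mc, 1.0 + M - mc))


def estimate_h2_from_beta(
    beta: np.ndarray, ld: LDMatrix, floor: float = 1e-4
) -> tuple[float, bool]:
    """h2 = beta' R beta over the stored nonzeros.

    The windowed R may be indefinite, so a negative quadratic form is
    floored (flagged via the second return value).
    """
    beta = np.asarray(beta, dtype=np.float64)
    q = float(beta @ (ld.R @ beta))
    if q < floor:
        return floor, True
    return q, False


def run_auto_chain(
    beta_hat: ScaledBetas,
    ld: LDMatrix,
    init_p: float,
    init_h2: float,
    burn_in: int = 500,
    num_iter: int = 500,
    seed: int = 0,
    update_hyper: bool = True,
) -> AutoChain:
    """One auto chain; ``update_hyper=False`` freezes (p, h2), making the
    chain identical to ``run_gibbs`` at the same seed."""
    from . import _kernels

    indptr, indices, data = ld.csr_arrays()
    omega, beta, p_traj, h2_traj, diverged, done = _kernels.gibbs_chain(
        indptr,
        indices,
        data,
        beta_hat.beta_hat,
        beta_hat.n,
        float(beta_hat.m),
        float(init_p),
        float(init_h2),
        False,
        int(burn_in),
        int(num_iter),
        _chain_seed(seed, 0),
        bool(update_hyper),
        1e-4,
        100,
    )
    post = slice(burn_in, max(done, burn_in + 1))
    return AutoChain(
        init_p=float(init_p),
        init_h2=float(init_h2),
        p_traj=p_traj,
        h2_traj=h2_traj,
        beta=beta,
        omega=omega,
        p_hat=float(np.mean(p_traj[post])),
        h2_hat=float(np.mean(h2_traj[post])),
        diverged=bool(diverged),
    )


def run_auto(
    beta_hat: ScaledBetas,
    ld: LDMatrix,
    n_chains: int = 30,
    burn_in: int = 500,
    num_iter: int = 500,
    seed: int = 0,
    init_h2: float | None = None,
    ref_panel: GenotypePanel | None = None,
) -> LDpredAuto:
    """Fit the full multi-chain auto model and return the fitted estimator."""
    return LDpredAuto(
        n_chains=n_chains, burn_in=burn_in, num_iter=num_iter, init_h2=init_h2,
        random_state=seed,
    ).fit(beta_hat, ld, ref_panel=ref_panel)


def auto_sparse(
    beta_hat: ScaledBetas,
    ld: LDMatrix,
    p_hat: float,
    h2_hat: float,
    burn_in: int = 500,
    num_iter: int = 500,
    seed: int = 0,
) -> PgsResult:
    """Sparse companion of the auto model: one sparse grid run at (p_hat, h2_hat)."""
    est = LDpredGibbs(
        p=p_hat, h2=h2_hat, sparse=True, burn_in=burn_in, num_iter=num_iter,
        random_state=seed,
    ).fit(beta_hat, ld)
    return est.result_
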