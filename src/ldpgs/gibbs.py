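"""Functional surface over the Gibbs-sampler estimators.

These are thin wrappers around :class:`~ldpgs.models.LDpredInf`,
:class:`~ldpgs.models.LDpredGibbs` and :class:`~ldpgs.models.LDpredGrid`,
plus pure-Python reference implementations of the per-variant update
quantities (residualized effect, causal posterior probability, one sweep)
that the compiled kernel is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ld import LDMatrix
from .models import (  # noqa: F401  (re-exported surface)
    HyperParams,
    LDpredGibbs,
    LDpredGrid,
    LDpredInf,
    PgsResult,
    default_grid,
)
from .prep import ScaledBetas

_SHRINK_CAP = 1e12


def solve_inf(beta_hat: ScaledBetas, ld: LDMatrix, h2: float) -> np.ndarray:
    """Analytic infinitesimal solution (R + M/(n h2) I) x = beta_hat."""
    est = LDpredInf(h2=h2).fit(beta_hat, ld)
    return est.beta_


def residualized_effect(j: int, beta_hat_j: float, beta: np.ndarray, rtimesbeta: np.ndarray,
                        diag_j: float = 1.0) -> float:
    """Marginal effect of variant j with the LD contribution of all other
    current effects removed, computed from the cached R.beta product."""
    return float(beta_hat_j - rtimesbeta[j] + diag_j * beta[j])


def causal_posterior_prob(btilde, p: float, h2: float, n_j, M: int):
    """Posterior probability that a variant is causal (stable form).

    Evaluates 1 / (1 + ((1-p)/p) sqrt(1 + n h2/(M p))
    exp(-n btilde^2 / (2 (1 + M p/(n h2))))); the exponent is always
    non-positive, so no overflow occurs however large n * btilde^2 gets.
    """
    btilde = np.asarray(btilde, dtype=np.float64)
    n_j = np.asarray(n_j, dtype=np.float64)
    if p >= 1.0:
        return np.ones_like(btilde) if btilde.ndim else 1.0
    s = np.minimum(M * p / (n_j * h2), _SHRINK_CAP)
    shrink = 1.0 / (1.0 + s)
    odds = ((1.0 - p) / p) * np.sqrt(1.0 + n_j * h2 / (M * p)) * np.exp(
        -0.5 * n_j * btilde**2 * shrink
    )
    out = 1.0 / (1.0 + odds)
    return out if out.ndim else float(out)


@dataclass
class GibbsState:
    """Mutable state of one reference-implementation Gibbs chain."""

    beta: np.ndarray
    rtimesbeta: np.ndarray
    omega_sum: np.ndarray
    p_cur: float
    h2_cur: float
    rng: np.random.Generator
    sweep: int = 0
    diverged: bool = False

    @classmethod
    def init(cls, m: int, hp: HyperParams, seed: int) -> "GibbsState":
        return cls(
            beta=np.zeros(m),
            rtimesbeta=np.zeros(m),
            omega_sum=np.zeros(m),
            p_cur=hp.p,
            h2_cur=hp.h2,
            rng=np.random.default_rng(seed),
        )


def gibbs_sweep(
    state: GibbsState,
    beta_hat: ScaledBetas,
    ld: LDMatrix,
    hp: HyperParams,
    M: int | None = None,
) -> np.ndarray:
    """One full pass over all variants (pure-Python reference path).

    Updates ``state`` in place and returns the per-sweep posterior means
    omega.  The compiled kernel in ``_kernels`` is the production path;
    this implementation exists as an independently-written oracle and for
    inspecting single sweeps.
    """
    R = ld.R
    m = beta_hat.m
    M = M if M is not None else m
    omega = np.zeros(m)
    p, h2 = hp.p, hp.h2
    for j in range(m):
        nj = beta_hat.n[j]
        btilde = residualized_effect(j, beta_hat.beta_hat[j], state.beta, state.rtimesbeta)
        if not np.isfinite(btilde):
            state.diverged = True
            break
        pbar = causal_posterior_prob(btilde, p, h2, nj, M)
        shrink = 1.0 / (1.0 + min(M * p / (nj * h2), _SHRINK_CAP))
        if hp.sparse and pbar < p:
            new, om = 0.0, 0.0
        else:
            om = pbar * shrink * btilde
            if state.rng.random() < pbar:
                new = shrink * btilde + state.rng.standard_normal() * np.sqrt(shrink / nj)
            else:
                new = 0.0
        if abs(new) > 10.0:
            state.diverged = True
        d = new - state.beta[j]
        if d != 0.0:
            state.beta[j] = new
            col = slice(R.indptr[j], R.indptr[j + 1])
            state.rtimesbeta[R.indices[col]] += R.data[col] * d
        omega[j] = om
    state.sweep += 1
    return omega


def run_gibbs(
    beta_hat: ScaledBetas,
    ld: LDMatrix,
    hp: HyperParams,
    burn_in: int = 100,
    num_iter: int = 500,
    seed: int = 0,
) -> PgsResult:
    """Posterior-mean effects from one chain at fixed hyper-parameters."""
    est = LDpredGibbs(
        p=hp.p, h2=hp.h2, sparse=hp.sparse, burn_in=burn_in, num_iter=num_iter,
        random_state=seed,
    ).fit(beta_hat, ld)
    return est.result_


def run_grid(
    beta_hat: ScaledBetas,
    ld: LDMatrix,
    grid: list[HyperParams],
    burn_in: int = 100,
    num_iter: int = 500,
    seed: int = 0,
    threads: int = 1,
) -> list[PgsResult]:
    """One independent chain per grid entry; thread-count independent."""
    est = LDpredGrid(
        grid=grid, burn_in=burn_in, num_iter=num_iter, random_state=seed, n_jobs=threads
    ).fit(beta_hat, ld)
    return est.results_
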