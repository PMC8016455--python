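"""Numba kernels for the spike-and-slab Gibbs sampler.

The LD matrix is passed as symmetric CSR arrays (indptr/indices/data, the
diagonal stored).  One variant update computes the residualized marginal
effect from the cached R.beta product, the causal posterior probability in
its numerically stable form (no overflow for arbitrarily large n*btilde^2),
samples the effect from the slab with that probability, and updates the
cache incrementally along the variant's stored column.  The cache is
refreshed from scratch every ``refresh_every`` sweeps to bound
floating-point drift.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: cap on M*p/(n*h2) so the degenerate h2->0 / p->0 corner stays finite
_SHRINK_CAP = 1e12


@njit(cache=True)
def _recompute_rbeta(indptr, indices, data, beta, rbeta):
    rbeta[:] = 0.0
    for j in range(beta.size):
        bj = beta[j]
        if bj != 0.0:
            for k in range(indptr[j], indptr[j + 1]):
                rbeta[indices[k]] += data[k] * bj


@njit(cache=True)
def _causal_prob(btilde, p, h2, nj, M):
    """Stable evaluation of the posterior causal probability."""
    if p >= 1.0:
        return 1.0
    s = M * p / (nj * h2)
    if s > _SHRINK_CAP:
        s = _SHRINK_CAP
    shrink = 1.0 / (1.0 + s)
    odds = ((1.0 - p) / p) * np.sqrt(1.0 + nj * h2 / (M * p)) * np.exp(
        -0.5 * nj * btilde * btilde * shrink
    )
    return 1.0 / (1.0 + odds)


@njit(cache=True)
def gibbs_chain(
    indptr,
    indices,
    data,
    beta_hat,
    n_per,
    M,
    p_init,
    h2_init,
    sparse,
    burn_in,
    num_iter,
    seed,
    auto_update,
    h2_floor,
    refresh_every,
):
    """Run one Gibbs chain; returns posterior means and diagnostics.

    With ``auto_update`` the hyper-parameters evolve between sweeps: p is
    drawn from Beta(1 + Mc, 1 + M - Mc) with Mc the count of currently
    nonzero effects, and h2 is set to beta' R beta (floored at h2_floor).

    Returns (omega_mean, beta, p_traj, h2_traj, diverged, sweeps_done).
    """
    np.random.seed(seed)
    m = beta_hat.size
    beta = np.zeros(m)
    rbeta = np.zeros(m)
    omega = np.zeros(m)
    omega_sum = np.zeros(m)
    total = burn_in + num_iter
    p_traj = np.empty(total)
    h2_traj = np.empty(total)
    p = p_init
    h2 = h2_init
    diverged = False
    n_hot = 0
    sweeps_done = 0
    for sweep in range(total):
        if refresh_every > 0 and sweep > 0 and sweep % refresh_every == 0:
            _recompute_rbeta(indptr, indices, data, beta, rbeta)
        for j in range(m):
            nj = n_per[j]
            btilde = beta_hat[j] - rbeta[j] + beta[j]
            if not np.isfinite(btilde):
                diverged = True
                break
            pbar = _causal_prob(btilde, p, h2, nj, M)
            s = M * p / (nj * h2)
            if s > _SHRINK_CAP:
                s = _SHRINK_CAP
            shrink = 1.0 / (1.0 + s)
            if sparse and pbar < p:
                new = 0.0
                om = 0.0
            else:
                om = pbar * shrink * btilde
                if np.random.random() < pbar:
                    new = shrink * btilde + np.random.normal() * np.sqrt(shrink / nj)
                else:
                    new = 0.0
            if np.abs(new) > 10.0:
                diverged = True
                break
            d = new - beta[j]
            if d != 0.0:
                beta[j] = new
                for k in range(indptr[j], indptr[j + 1]):
                    rbeta[indices[k]] += data[k] * d
            omega[j] = om
        if diverged:
            for t in range(sweep, total):
                p_traj[t] = p
                h2_traj[t] = h2
            break
        if auto_update:
            mc = 0
            for j in range(m):
                if beta[j] != 0.0:
                    mc += 1
            p = np.random.beta(1.0 + mc, 1.0 + M - mc)
            h2v = 0.0
            for j in range(m):
                h2v += beta[j] * rbeta[j]
            if h2v < h2_floor:
                h2v = h2_floor
            h2 = h2v
            if h2 > 1.5:
                n_hot += 1
                if n_hot >= 10:
                    diverged = True
            else:
                n_hot = 0
        p_traj[sweep] = p
        h2_traj[sweep] = h2
        if sweep >= burn_in:
            omega_sum += omega
        sweeps_done = sweep + 1
        if diverged:
            break
    n_avg = max(sweeps_done - burn_in, 1)
    return omega_sum / n_avg, beta, p_traj, h2_traj, diverged, sweeps_done
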