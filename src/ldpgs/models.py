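"""Estimator classes for the three polygenic-score models.

All estimators follow the scikit-learn protocol: hyper-parameters in
``__init__``, ``fit(sumstats, ld)`` producing trailing-underscore
attributes, ``predict(panel)`` returning per-individual polygenic scores,
and ``get_params``/``set_params`` for composition with model selection.

The model for standardized effects is a spike and slab: beta_j ~
N(0, h2/(M p)) with probability p, else exactly 0.  ``LDpredInf`` is the
analytic p=1 solution, ``LDpredGibbs``/``LDpredGrid`` run the Gibbs sampler
at fixed hyper-parameters (optionally over a grid, optionally with the
sparse rule that sets effects with causal probability below p to exact
zero), and ``LDpredAuto`` estimates (p, h2) inside the sampler across many
chains and averages the chains that survive a MAD filter on predictor SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.base import BaseEstimator

from . import _kernels
from .io import GenotypePanel
from .ld import LDMatrix, ld_scores
from .prep import ScaledBetas, ldsc_h2_constrained, scale_to_std


@dataclass(frozen=True)
class HyperParams:
    """One spike-and-slab configuration: causal proportion, h2, sparse rule."""

    p: float
    h2: float
    sparse: bool = False

    def __post_init__(self):
        if not (0 < self.p <= 1):
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if not self.h2 > 0:
            raise ValueError(f"h2 must be positive, got {self.h2}")


@dataclass
class PgsResult:
    """Posterior-mean effects for one model, on both scales."""

    omega: np.ndarray  # standardized-scale posterior means
    effects: np.ndarray  # allele-scale effects = omega * scale
    hp: HyperParams | None
    diverged: bool = False

    @property
    def sparsity(self) -> float:
        """Share of exactly-zero allele-scale effects."""
        return float(np.mean(self.effects == 0.0))


def default_grid(h2_ldsc: float) -> list[HyperParams]:
    """The default 126-model hyper-parameter grid.

    21 log-spaced causal proportions on [1e-5, 1], h2 in {0.7, 1, 1.4}
    times the LDSC estimate, sparse off/on.
    """
    if not h2_ldsc > 0:
        raise ValueError("h2_ldsc must be positive")
    p_seq = np.logspace(-5, 0, 21)
    grid = []
    for sparse in (False, True):
        for mult in (0.7, 1.0, 1.4):
            for p in p_seq:
                grid.append(HyperParams(p=float(p), h2=mult * h2_ldsc, sparse=sparse))
    return grid


def auto_init_p(n_chains: int = 30) -> np.ndarray:
    """Default dispersed initial causal proportions: log-spaced on [1e-4, 0.9]."""
    return np.exp(np.linspace(np.log(1e-4), np.log(0.9), n_chains))


def _as_scaled(sumstats) -> ScaledBetas:
    if isinstance(sumstats, ScaledBetas):
        return sumstats
    if isinstance(sumstats, pd.DataFrame):
        return scale_to_std(sumstats)
    raise TypeError("sumstats must be a ScaledBetas or a summary-statistics DataFrame")


def _check_alignment(scaled: ScaledBetas, ld: LDMatrix):
    if scaled.m != ld.m:
        raise ValueError(
            f"sumstats ({scaled.m} variants) and LD matrix ({ld.m}) are not aligned; "
            "run match_variants first"
        )


def _chain_seed(random_state: int, index: int) -> int:
    """Deterministic per-chain seed; independent of execution order/threads."""
    return int(np.random.SeedSequence((int(random_state), int(index))).generate_state(1)[0] % (2**31))


def _ldsc_from_scaled(scaled: ScaledBetas, ld: LDMatrix) -> float:
    chi2 = (scaled.beta_hat**2) * scaled.n
    return ldsc_h2_constrained(chi2, ld_scores(ld), scaled.n, M=scaled.m)


class _PgsEstimator(BaseEstimator):
    """Shared fit plumbing and allele-scale prediction."""

    def _prepare(self, sumstats, ld: LDMatrix) -> ScaledBetas:
        scaled = _as_scaled(sumstats)
        _check_alignment(scaled, ld)
        self.ld_ = ld
        self.scale_ = scaled.scale
        return scaled

    def predict(self, panel: GenotypePanel) -> np.ndarray:
        """Polygenic scores on a genotype panel (variants matched on chr/pos)."""
        from .evaluate import compute_pgs

        effects = pd.DataFrame(
            {
                "chr": self.ld_.variants["chr"],
                "pos": self.ld_.variants["pos"],
                "a0": self.ld_.variants["a0"],
                "a1": self.ld_.variants["a1"],
                "effect": self.effects_,
            }
        )
        return compute_pgs(panel, effects)


class LDpredInf(_PgsEstimator):
    """Analytic infinitesimal model: every variant is causal.

    Solves (R + M/(n h2) I) beta = beta_hat with a sparse direct solver.
    When ``h2`` is None it is estimated by constrained LD score regression
    at fit time.
    """

    def __init__(self, h2: float | None = None, rtol: float = 1e-10):
        self.h2 = h2
        self.rtol = rtol

    def fit(self, sumstats, ld: LDMatrix):
        scaled = self._prepare(sumstats, ld)
        h2 = self.h2 if self.h2 is not None else _ldsc_from_scaled(scaled, ld)
        n_mean = float(np.mean(scaled.n))
        M = scaled.m
        A = (ld.R + (M / (n_mean * h2)) * sp.eye(M)).tocsc()
        x = spla.spsolve(A, scaled.beta_hat)
        resid = np.linalg.norm(A @ x - scaled.beta_hat)
        rel = resid / max(np.linalg.norm(scaled.beta_hat), 1e-300)
        if not np.isfinite(rel) or rel > self.rtol:
            raise RuntimeError(f"infinitesimal solver did not converge: relative residual {rel:.3e}")
        self.h2_used_ = h2
        self.beta_ = x
        self.effects_ = scaled.back_scale(x)
        return self


class LDpredGibbs(_PgsEstimator):
    """One Gibbs chain at fixed (p, h2), optionally with the sparse rule.

    ``h2=None`` triggers constrained-LDSC estimation at fit time.  ``M``
    overrides the variant count used in the prior (defaults to the number
    of fitted variants; useful when fitting one chromosome of a
    genome-wide analysis).
    """

    def __init__(
        self,
        p: float = 0.1,
        h2: float | None = None,
        sparse: bool = False,
        burn_in: int = 100,
        num_iter: int = 500,
        refresh_every: int = 100,
        random_state: int = 0,
        M: int | None = None,
    ):
        self.p = p
        self.h2 = h2
        self.sparse = sparse
        self.burn_in = burn_in
        self.num_iter = num_iter
        self.refresh_every = refresh_every
        self.random_state = random_state
        self.M = M

    def fit(self, sumstats, ld: LDMatrix):
        scaled = self._prepare(sumstats, ld)
        h2 = self.h2 if self.h2 is not None else _ldsc_from_scaled(scaled, ld)
        hp = HyperParams(p=self.p, h2=h2, sparse=self.sparse)
        M = self.M if self.M is not None else scaled.m
        indptr, indices, data = ld.csr_arrays()
        omega, beta, _, _, diverged, _ = _kernels.gibbs_chain(
            indptr,
            indices,
            data,
            scaled.beta_hat,
            scaled.n,
            float(M),
            hp.p,
            hp.h2,
            hp.sparse,
            int(self.burn_in),
            int(self.num_iter),
            _chain_seed(self.random_state, 0),
            False,
            1e-4,
            int(self.refresh_every),
        )
        self.hp_ = hp
        self.diverged_ = bool(diverged)
        self.beta_ = beta
        self.omega_ = omega
        self.effects_ = scaled.back_scale(omega)
        self.result_ = PgsResult(omega=omega, effects=self.effects_, hp=hp, diverged=self.diverged_)
        return self


class LDpredGrid(_PgsEstimator):
    """Gibbs sampler over a grid of (p, h2, sparse) configurations.

    ``grid=None`` uses the default 126-model grid anchored on the LDSC h2
    estimate.  Each model runs an independent chain with a seed derived
    from (random_state, model index), so results do not depend on the
    number of worker threads.  After fitting, ``select_best`` picks a model
    by the Z-score of the phenotype-on-score regression in a validation
    panel.
    """

    def __init__(
        self,
        grid: list[HyperParams] | None = None,
        burn_in: int = 100,
        num_iter: int = 500,
        refresh_every: int = 100,
        random_state: int = 0,
        n_jobs: int = 1,
    ):
        self.grid = grid
        self.burn_in = burn_in
        self.num_iter = num_iter
        self.refresh_every = refresh_every
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, sumstats, ld: LDMatrix):
        scaled = self._prepare(sumstats, ld)
        grid = self.grid if self.grid is not None else default_grid(_ldsc_from_scaled(scaled, ld))
        if not grid:
            raise ValueError("empty hyper-parameter grid")
        indptr, indices, data = ld.csr_arrays()

        def one(i: int, hp: HyperParams) -> PgsResult:
            omega, _, _, _, diverged, _ = _kernels.gibbs_chain(
                indptr,
                indices,
                data,
                scaled.beta_hat,
                scaled.n,
                float(scaled.m),
                hp.p,
                hp.h2,
                hp.sparse,
                int(self.burn_in),
                int(self.num_iter),
                _chain_seed(self.random_state, i),
                False,
                1e-4,
                int(self.refresh_every),
            )
            return PgsResult(
                omega=omega, effects=scaled.back_scale(omega), hp=hp, diverged=bool(diverged)
            )

        if self.n_jobs and self.n_jobs != 1:
            from joblib import Parallel, delayed

            results = Parallel(n_jobs=self.n_jobs, backend="threading")(
                delayed(one)(i, hp) for i, hp in enumerate(grid)
            )
        else:
            results = [one(i, hp) for i, hp in enumerate(grid)]
        self.grid_ = list(grid)
        self.results_ = results
        self.best_index_ = 0
        self.effects_ = results[0].effects
        return self

    def candidate_scores(self, panel: GenotypePanel) -> np.ndarray:
        """Per-individual scores for every grid model (n x n_models)."""
        cols = []
        for res in self.results_:
            self.effects_ = res.effects
            cols.append(self.predict(panel))
        self.effects_ = self.results_[self.best_index_].effects
        return np.column_stack(cols)

    def select_best(self, panel: GenotypePanel, phenotype: np.ndarray) -> int:
        """Pick the grid model maximizing the phenotype~PGS regression Z-score."""
        from .evaluate import zscore_select

        scores = self.candidate_scores(panel)
        self.best_index_ = zscore_select(phenotype, scores)
        self.effects_ = self.results_[self.best_index_].effects
        return self.best_index_


@dataclass
class AutoChain:
    """One auto-model chain: dispersed init, hyper-parameter trajectories."""

    init_p: float
    init_h2: float
    p_traj: np.ndarray
    h2_traj: np.ndarray
    beta: np.ndarray  # final sampled standardized effects
    omega: np.ndarray  # posterior-mean standardized effects
    p_hat: float
    h2_hat: float
    diverged: bool
    predictor_sd: float = field(default=np.nan)


class LDpredAuto(_PgsEstimator):
    """Auto model: p and h2 are learned inside the Gibbs sampler.

    After every sweep, p is redrawn from Beta(1 + Mc, 1 + M - Mc) where Mc
    counts the currently nonzero effects, and h2 is set to beta' R beta.
    ``n_chains`` chains start from dispersed initial p values; chains whose
    predictor standard deviation falls more than three median absolute
    deviations from the median are discarded and the rest averaged.
    """

    def __init__(
        self,
        n_chains: int = 30,
        burn_in: int = 500,
        num_iter: int = 500,
        init_h2: float | None = None,
        init_p: np.ndarray | None = None,
        refresh_every: int = 100,
        random_state: int = 0,
        n_jobs: int = 1,
    ):
        self.n_chains = n_chains
        self.burn_in = burn_in
        self.num_iter = num_iter
        self.init_h2 = init_h2
        self.init_p = init_p
        self.refresh_every = refresh_every
        self.random_state = random_state
        self.n_jobs = n_jobs

    def _run_chain(
        self, scaled: ScaledBetas, ld: LDMatrix, init_p: float, init_h2: float, seed: int
    ) -> AutoChain:
        indptr, indices, data = ld.csr_arrays()
        omega, beta, p_traj, h2_traj, diverged, done = _kernels.gibbs_chain(
            indptr,
            indices,
            data,
            scaled.beta_hat,
            scaled.n,
            float(scaled.m),
            float(init_p),
            float(init_h2),
            False,
            int(self.burn_in),
            int(self.num_iter),
            int(seed),
            True,
            1e-4,
            int(self.refresh_every),
        )
        post = slice(self.burn_in, max(done, self.burn_in + 1))
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

    def fit(self, sumstats, ld: LDMatrix, ref_panel: GenotypePanel | None = None):
        scaled = self._prepare(sumstats, ld)
        init_h2 = self.init_h2 if self.init_h2 is not None else _ldsc_from_scaled(scaled, ld)
        init_p = self.init_p if self.init_p is not None else auto_init_p(self.n_chains)
        init_p = np.asarray(init_p, dtype=np.float64)
        tasks = [
            (float(p0), _chain_seed(self.random_state, i)) for i, p0 in enumerate(init_p)
        ]
        if self.n_jobs and self.n_jobs != 1:
            from joblib import Parallel, delayed

            chains = Parallel(n_jobs=self.n_jobs, backend="threading")(
                delayed(self._run_chain)(scaled, ld, p0, init_h2, s) for p0, s in tasks
            )
        else:
            chains = [self._run_chain(scaled, ld, p0, init_h2, s) for p0, s in tasks]
        self.chains_ = chains
        result, kept = combine_chains(chains, scaled, ld, ref_panel=ref_panel)
        self.kept_ = kept
        self.result_ = result
        self.omega_ = result.omega
        self.effects_ = result.effects
        self.p_hat_ = float(np.mean([chains[i].p_hat for i in kept]))
        self.h2_hat_ = float(np.mean([chains[i].h2_hat for i in kept]))
        return self


def combine_chains(
    chains: list[AutoChain],
    scaled: ScaledBetas,
    ld: LDMatrix,
    ref_panel: GenotypePanel | None = None,
) -> tuple[PgsResult, list[int]]:
    """MAD-filter auto chains on predictor SD and average the survivors.

    The predictor SD per chain is the standard deviation of its polygenic
    score on ``ref_panel`` when genotypes are available, else the
    sqrt(omega' R omega) proxy.  Chains within three median absolute
    deviations of the median SD are kept; their posterior-mean effects are
    averaged elementwise.
    """
    alive = [i for i, c in enumerate(chains) if not c.diverged]
    if not alive:
        raise ValueError(
            "all auto chains diverged; check summary-statistics QC before rerunning"
        )
    sds = np.empty(len(chains))
    sds[:] = np.nan
    for i in alive:
        c = chains[i]
        if ref_panel is not None:
            from .evaluate import compute_pgs

            effects = pd.DataFrame(
                {
                    "chr": ld.variants["chr"],
                    "pos": ld.variants["pos"],
                    "a0": ld.variants["a0"],
                    "a1": ld.variants["a1"],
                    "effect": scaled.back_scale(c.omega),
                }
            )
            sds[i] = float(np.std(compute_pgs(ref_panel, effects)))
        else:
            q = float(c.omega @ (ld.R @ c.omega))
            sds[i] = float(np.sqrt(max(q, 0.0)))
        c.predictor_sd = sds[i]
    med = float(np.median(sds[alive]))
    mad = float(np.median(np.abs(sds[alive] - med)))
    kept = [i for i in alive if abs(sds[i] - med) <= 3.0 * mad]
    omega = np.mean([chains[i].omega for i in kept], axis=0)
    result = PgsResult(omega=omega, effects=scaled.back_scale(omega), hp=None, diverged=False)
    return result, kept
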