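"""Synthetic genotypes, liability-threshold phenotypes and GWAS output.

The genotype generator uses a latent-Gaussian threshold scheme: each
haplotype is a stationary AR(1) Gaussian process along the chromosome
(correlation rho^|j-k| between latent values) thresholded at the normal
quantile of each variant's allele frequency, and an individual's dosage is
the sum over two independent haplotypes.  This gives cheap, reproducible
panels with tunable local LD; it does not emulate recombination hotspots,
population structure or relatedness.

Binary phenotypes follow the liability threshold model: liability =
genetic component + residual, with the genetic component rescaled so its
in-sample variance is exactly h2 and the residual orthogonalized and
rescaled so the total in-sample variance is exactly 1; cases are
individuals whose liability exceeds the (1 - prevalence) normal quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import GenotypePanel
from .ld import LDMatrix
from .prep import ScaledBetas, effective_sample_size

logger = logging.getLogger(__name__)


@dataclass
class SimSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror a desk-scale version of a polygenicity scenario:
    h2 = 0.3, prevalence 15%, 2% of variants causal, moderate local LD.
    """

    n_individuals: int = 20_000
    m_variants: int = 2_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    rho: float = 0.6  # latent AR(1) LD decay per adjacent variant
    n_causal: int = 40
    causal_region: tuple[int, int] | None = None  # variant-index interval, else genome-wide
    h2: float = 0.3
    prevalence: float = 0.15
    trait: str = "binary"
    spacing_bp: int = 5_000
    hla_like: bool = True  # include a compressed-recombination region in the map
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.h2 <= 1):
            raise ValueError("h2 must be in (0, 1]")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_causal > self.m_variants:
            raise ValueError("cannot have more causal variants than variants")


def simu_genotypes(spec: SimSpec) -> tuple[GenotypePanel, dict]:
    """Generate a genotype panel plus a matching genetic map.

    The map runs at ~1 cM/Mb except, when ``hla_like`` is set, over the
    middle fifth of the chromosome, where recombination is compressed to
    3/8 of that rate (an 8 Mb stretch spanning only 3 cM, like the HLA
    region).
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_individuals, spec.m_variants
    maf = rng.uniform(*spec.maf_range, size=m)
    thresh = norm.ppf(1.0 - maf)  # latent value above threshold -> carry the effect allele

    dosage = np.zeros((n, m), dtype=np.float64)
    c = np.sqrt(1.0 - spec.rho**2)
    for _ in range(2):  # two haplotypes
        z = rng.standard_normal(n)
        dosage[:, 0] += z > thresh[0]
        for j in range(1, m):
            z = spec.rho * z + c * rng.standard_normal(n)
            dosage[:, j] += z > thresh[j]

    if spec.missing_rate > 0:
        mask = rng.random((n, m)) < spec.missing_rate
        dosage[mask] = np.nan

    pos = (1 + np.arange(m)) * spec.spacing_bp
    # strand-unambiguous allele pairs only (no A/T or C/G)
    bases = np.array(list("ACGT"))
    safe_other = {"A": ["C", "G"], "C": ["A", "T"], "G": ["A", "T"], "T": ["C", "G"]}
    a1 = bases[rng.integers(0, 4, size=m)]
    pick = rng.integers(0, 2, size=m)
    a0 = np.array([safe_other[b][k] for b, k in zip(a1, pick)])
    variants = pd.DataFrame(
        {"chr": "1", "pos": pos, "a0": a0, "a1": a1, "id": [f"v{j}" for j in range(m)]}
    )
    panel = GenotypePanel(dosages=dosage, variants=variants)

    span = pos[-1]
    if spec.hla_like:
        b0, b1 = 0.4 * span, 0.6 * span
        rate = 1.0 / 1e6  # cM per bp
        slow = rate * 3.0 / 8.0
        knots_bp = np.array([1.0, b0, b1, float(span)])
        knots_cm = np.array(
            [0.0, b0 * rate, b0 * rate + (b1 - b0) * slow,
             b0 * rate + (b1 - b0) * slow + (span - b1) * rate]
        )
    else:
        knots_bp = np.array([1.0, float(span)])
        knots_cm = np.array([0.0, span / 1e6])
    gmap = {"1": (knots_bp, knots_cm)}
    return panel, gmap


@dataclass
class LtmPhenotype:
    liability: np.ndarray
    phenotype: np.ndarray  # 0/1 for binary traits, the liability for linear
    causal_idx: np.ndarray
    weights: np.ndarray  # standardized-scale causal weights, post-rescaling


def simu_pheno_ltm(panel: GenotypePanel, spec: SimSpec, rng=None) -> LtmPhenotype:
    """Liability-threshold phenotype with exact in-sample variance scaling."""
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    n, m = panel.dosages.shape
    lo, hi = spec.causal_region if spec.causal_region is not None else (0, m)
    candidates = np.arange(lo, hi)
    mono = panel.monomorphic()
    causal = rng.choice(candidates, size=spec.n_causal, replace=False)
    n_resampled = 0
    while mono[causal].any():
        bad = causal[mono[causal]]
        pool = np.setdiff1d(candidates[~mono[candidates]], causal)
        if len(pool) < len(bad):
            raise ValueError("not enough polymorphic variants in the causal region")
        causal = np.concatenate([causal[~mono[causal]], rng.choice(pool, len(bad), False)])
        n_resampled += len(bad)
    if n_resampled:
        logger.info("resampled %d monomorphic causal variants", n_resampled)
    causal.sort()

    G = panel.dosages[:, causal]
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G = G.copy()
        G[idx] = np.take(col_mean, idx[1])
    Gt = (G - G.mean(axis=0)) / G.std(axis=0)

    w = rng.normal(0.0, np.sqrt(spec.h2 / spec.n_causal), size=spec.n_causal)
    g = Gt @ w
    g = g - g.mean()
    vg = g @ g / n
    sc = np.sqrt(spec.h2 / vg)
    g *= sc
    w *= sc

    eps = rng.normal(0.0, 1.0, size=n)
    # orthogonalize against the genetic component so the total variance is exact
    eps = eps - eps.mean()
    eps -= (eps @ g) / (g @ g) * g
    eps *= np.sqrt((1.0 - spec.h2) / (eps @ eps / n))
    liab = g + eps

    if spec.trait == "binary":
        pheno = (liab > norm.ppf(1.0 - spec.prevalence)).astype(np.int64)
    else:
        pheno = liab
    return LtmPhenotype(liability=liab, phenotype=pheno, causal_idx=causal, weights=w)


def run_gwas(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    trait: str = "linear",
) -> pd.DataFrame:
    """Per-variant simple-regression GWAS returning a summary-statistics table.

    Linear traits use OLS with an intercept (vectorized over variants);
    binary traits use per-variant logistic regression via statsmodels, with
    non-converging variants dropped.  ``n`` is the per-variant non-missing
    count (for binary traits the effective sample size, with case/control
    counts attached).
    """
    y = np.asarray(phenotype, dtype=np.float64)
    X = panel.dosages
    n, m = X.shape
    if len(y) != n:
        raise ValueError("phenotype length does not match the panel")
    out = panel.variants[["chr", "pos", "a0", "a1"]].copy()

    if trait == "linear":
        ok = ~np.isnan(X)
        nj = ok.sum(axis=0).astype(np.float64)
        Xz = np.where(ok, X, 0.0)
        sx = Xz.sum(axis=0)
        sy = ok.T @ y
        mx = sx / nj
        my = sy / nj
        sxx = (Xz**2).sum(axis=0) - nj * mx**2
        sxy = Xz.T @ y - nj * mx * my
        syy = ok.T @ (y**2) - nj * my**2
        with np.errstate(divide="ignore", invalid="ignore"):
            gamma = sxy / sxx
            ssr = syy - gamma * sxy
            se = np.sqrt(ssr / (nj - 2) / sxx)
        out["gamma_hat"] = gamma
        out["se_gamma"] = se
        out["n"] = nj
        bad = ~np.isfinite(gamma) | ~(se > 0)
        if bad.any():
            logger.info("dropping %d monomorphic/degenerate variants from GWAS", int(bad.sum()))
            out = out.loc[~bad].reset_index(drop=True)
        return out

    if trait != "binary":
        raise ValueError(f"unknown trait type: {trait!r}")

    import statsmodels.api as sm

    ncase = int(y.sum())
    ncontrol = int(len(y) - ncase)
    neff = effective_sample_size(ncase, ncontrol)
    gammas, ses, keep = [], [], []
    for j in range(m):
        x = X[:, j]
        ok = ~np.isnan(x)
        design = np.column_stack([np.ones(ok.sum()), x[ok]])
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y[ok], design).fit(disp=0, maxiter=100)
            if not res.mle_retvals.get("converged", False):
                raise RuntimeError("no convergence")
            gammas.append(res.params[1])
            ses.append(res.bse[1])
            keep.append(j)
        except Exception:
            logger.info("logistic GWAS did not converge for variant %d; dropped", j)
    out = out.iloc[keep].reset_index(drop=True)
    out["gamma_hat"] = gammas
    out["se_gamma"] = ses
    out["ncase"] = ncase
    out["ncontrol"] = ncontrol
    out["n"] = neff
    bad = ~(out["se_gamma"] > 0)
    if bad.any():
        out = out.loc[~bad].reset_index(drop=True)
    return out


def simulate_sumstats_model(
    m: int = 2_000,
    n: int = 20_000,
    p: float = 0.02,
    h2: float = 0.3,
    rho: float = 0.6,
    window_cM: float = 1.0,
    spacing_cM: float = 0.01,
    seed: int = 0,
) -> tuple[ScaledBetas, np.ndarray, LDMatrix]:
    """Standardized summary statistics drawn exactly from the spike-and-slab
    model: beta_hat ~ N(R beta, R/n) with AR(1) LD rho^|j-k|.

    The MVN noise uses the exact AR(1) Cholesky recurrence; the returned
    LDMatrix stores the analytic correlations inside the genetic-distance
    window (entries beyond it are negligible for the defaults, rho^100).
    Returns (scaled sumstats, true standardized effects, LD matrix).
    """
    rng = np.random.default_rng(seed)
    # fixed causal count (as in scenario tables), random positions
    n_causal = max(1, round(m * p))
    causal = rng.choice(m, size=n_causal, replace=False)
    beta = np.zeros(m)
    beta[causal] = rng.normal(0.0, np.sqrt(h2 / (m * p)), size=n_causal)

    k_max = min(int(np.ceil(window_cM / spacing_cM)), m)
    import scipy.sparse as sp

    offsets = np.arange(-k_max + 1, k_max)
    diags = [np.full(m - abs(k), rho ** abs(k)) for k in offsets]
    R = sp.diags(diags, offsets, format="csr")

    # exact-variance convention (as in the phenotype simulator): rescale the
    # causal effects so the genetic variance beta' R beta equals h2 exactly
    q = float(beta @ (R @ beta))
    if q > 0:
        beta *= np.sqrt(h2 / q)

    # mean R beta (truncation error <= rho^k_max) plus exact AR(1) noise
    mean = R @ beta
    z = rng.standard_normal(m)
    e = np.empty(m)
    e[0] = z[0]
    c = np.sqrt(1.0 - rho**2)
    for j in range(1, m):
        e[j] = rho * e[j - 1] + c * z[j]
    beta_hat = mean + e / np.sqrt(n)

    genpos = np.arange(m, dtype=np.float64) * spacing_cM
    variants = pd.DataFrame(
        {"chr": "1", "pos": 1 + np.arange(m) * 1000, "a0": "A", "a1": "C"}
    )
    ld = LDMatrix(R=R, genpos=genpos, variants=variants, window_cM=window_cM)
    scaled = ScaledBetas(
        beta_hat=beta_hat, scale=np.ones(m), n=np.full(m, float(n))
    )
    return scaled, beta, ld
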