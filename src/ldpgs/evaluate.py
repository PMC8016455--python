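"""Scoring individuals and evaluating polygenic predictors.

AUC uses the Mann-Whitney estimator (ties count one half) with a
nonparametric bootstrap over individuals for confidence intervals.  Model
selection among candidate scores uses the Z-score of the phenotype-on-score
regression, which is more robust than AUC when comparing many correlated
candidates.  The theoretical ceiling on AUC under the liability threshold
model has a closed normal-theory form in the heritability and prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .io import GenotypePanel


def compute_pgs(panel: GenotypePanel, effects) -> np.ndarray:
    """Per-individual polygenic scores: sum over variants of dosage * effect.

    ``effects`` is either an array aligned with the panel's variants, or a
    DataFrame with (chr, pos, a0, a1, effect) matched on position (swapped
    alleles flip the effect sign).  Missing dosages are imputed to the
    per-variant mean dosage.
    """
    X = panel.dosages
    if isinstance(effects, pd.DataFrame):
        meta = panel.variants.reset_index(drop=True).copy()
        meta["_col"] = np.arange(len(meta))
        eff = effects.copy()
        eff["chr"] = eff["chr"].astype(str).str.replace("^chr", "", regex=True)
        merged = eff.merge(
            meta[["chr", "pos", "a0", "a1", "_col"]].rename(
                columns={"a0": "a0_ref", "a1": "a1_ref"}
            ),
            on=["chr", "pos"],
            how="inner",
        )
        same = (merged["a0"] == merged["a0_ref"]) & (merged["a1"] == merged["a1_ref"])
        swapped = (merged["a0"] == merged["a1_ref"]) & (merged["a1"] == merged["a0_ref"])
        merged = merged.loc[same | swapped]
        if merged.empty:
            raise ValueError("no overlapping variants between panel and effects")
        sign = np.where(swapped.loc[merged.index], -1.0, 1.0)
        cols = merged["_col"].to_numpy()
        vals = merged["effect"].to_numpy(np.float64) * sign
    else:
        vals = np.asarray(effects, dtype=np.float64)
        if vals.size != X.shape[1]:
            raise ValueError("effect vector length does not match the panel")
        cols = np.arange(X.shape[1])
    sub = X[:, cols]
    if np.isnan(sub).any():
        mean = np.nanmean(sub, axis=0)
        sub = np.where(np.isnan(sub), mean, sub)
    return sub @ vals


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC; tied scores count one half."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both cases and controls")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class AucSummary:
    estimate: float
    boot_mean: float
    ci_lower: float  # 2.5% quantile of the bootstrap AUCs
    ci_upper: float  # 97.5% quantile
    n_boot: int
    seed: int
    n_redrawn: int = 0  # single-class replicates redrawn

    def __post_init__(self):
        assert self.ci_lower <= self.boot_mean <= self.ci_upper


def auc_boot(
    scores: np.ndarray, labels: np.ndarray, n_boot: int = 10_000, seed: int = 0
) -> AucSummary:
    """Bootstrap the AUC over individuals (with replacement).

    Reports the mean of the n_boot bootstrap AUCs with their 2.5% and
    97.5% quantiles; replicates that draw a single class are redrawn so
    n_boot is fixed.
    """
    point = auc(scores, labels)
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n = scores.size
    vals = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            lb = labels[idx]
            s = int(lb.sum())
            if 0 < s < n:
                break
            n_redrawn += 1
        vals[b] = auc(scores[idx], lb)
    lo, hi = np.quantile(vals, [0.025, 0.975])
    return AucSummary(
        estimate=point,
        boot_mean=float(vals.mean()),
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_boot=n_boot,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def zscore_select(phenotype: np.ndarray, candidates: np.ndarray) -> int:
    """Index of the candidate score maximizing the regression Z-score.

    For each column, the phenotype is regressed on the score (simple
    linear regression with intercept) and Z = slope / SE computed;
    constant columns get Z = 0.  Ties resolve to the lowest index.
    """
    y = np.asarray(phenotype, dtype=np.float64)
    S = np.atleast_2d(np.asarray(candidates, dtype=np.float64))
    if S.shape[0] != y.size:
        S = S.T
    n = y.size
    yc = y - y.mean()
    Sc = S - S.mean(axis=0)
    sxx = (Sc**2).sum(axis=0)
    sxy = Sc.T @ yc
    syy = yc @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        ssr = syy - slope * sxy
        se = np.sqrt(ssr / (n - 2) / sxx)
        z = np.where(sxx > 0, np.abs(slope / se), 0.0)
    z = np.where(np.isfinite(z), z, 0.0)
    return int(np.argmax(z))


def max_theoretical_auc(h2: float, K: float) -> float:
    """Ceiling on AUC for a predictor equal to the true genetic liability.

    Normal-theory closed form under the liability threshold model: with
    threshold T = Phi^-1(1-K), z = phi(T), mean liabilities of cases
    i = z/K and controls i2 = -z/(1-K),

        AUC = Phi( (i - i2) h2 / sqrt(h2 [(1 - h2 i (i-T)) + (1 - h2 i2 (i2-T))]) ).
    """
    if not (0 < h2 <= 1):
        raise ValueError("h2 must be in (0, 1]")
    if not (0 < K < 1):
        raise ValueError("prevalence must be in (0, 1)")
    T = norm.ppf(1.0 - K)
    z = norm.pdf(T)
    i = z / K
    i2 = -z / (1.0 - K)
    num = (i - i2) * h2
    den = np.sqrt(h2 * ((1.0 - h2 * i * (i - T)) + (1.0 - h2 * i2 * (i2 - T))))
    return float(norm.cdf(num / den))
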