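"""Windowed sparse LD matrices keyed on genetic distance.

The correlation between two variants is stored only when they sit on the
same chromosome strictly less than ``window_cM`` centimorgans apart; the
window follows genetic rather than physical distance so that long-range LD
regions (the HLA region is ~8 Mb but only ~3 cM) are covered by a compact
window.  A 3 cM default is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import GenotypePanel


@dataclass
class LDMatrix:
    """Symmetric sparse Pearson-correlation matrix with window provenance."""

    R: sp.csr_matrix
    genpos: np.ndarray  # per-variant genetic position, cM
    variants: pd.DataFrame  # chr, pos, a0, a1
    window_cM: float
    monomorphic: np.ndarray = field(default=None)

    def __post_init__(self):
        self.R = self.R.tocsr()
        self.genpos = np.asarray(self.genpos, dtype=np.float64)
        if self.R.shape[0] != self.R.shape[1]:
            raise ValueError("R must be square")
        if self.R.shape[0] != len(self.genpos):
            raise ValueError("genpos length does not match R")
        if self.monomorphic is None:
            self.monomorphic = np.zeros(self.m, dtype=bool)

    @property
    def m(self) -> int:
        return self.R.shape[0]

    def csr_arrays(self):
        """(indptr, indices, data) of the symmetric CSR storage."""
        R = self.R
        return R.indptr.astype(np.int64), R.indices.astype(np.int64), R.data


def interpolate_genetic_pos(
    pos_bp: np.ndarray, chrom: np.ndarray, gmap: dict
) -> np.ndarray:
    """Piecewise-linear interpolation of bp positions onto the genetic map.

    Positions beyond the map ends are extrapolated linearly from the two
    terminal knots (constant for single-knot chromosomes).
    """
    pos_bp = np.asarray(pos_bp, dtype=np.float64)
    chrom = np.asarray(chrom).astype(str)
    out = np.empty_like(pos_bp)
    missing = sorted(set(chrom) - set(gmap))
    if missing:
        raise ValueError(f"chromosome(s) absent from genetic map: {missing}")
    for c in np.unique(chrom):
        mask = chrom == c
        bp, cm = gmap[str(c)]
        q = pos_bp[mask]
        val = np.interp(q, bp, cm)
        if len(bp) >= 2:
            lo_slope = (cm[1] - cm[0]) / (bp[1] - bp[0])
            hi_slope = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
            below = q < bp[0]
            above = q > bp[-1]
            val[below] = cm[0] + (q[below] - bp[0]) * lo_slope
            val[above] = cm[-1] + (q[above] - bp[-1]) * hi_slope
        out[mask] = val
    return out


def _pairwise_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation over individuals non-missing in both columns."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    xv = x[ok] - x[ok].mean()
    yv = y[ok] - y[ok].mean()
    den = np.sqrt((xv @ xv) * (yv @ yv))
    if den == 0:
        return 0.0
    return float((xv @ yv) / den)


def windowed_correlation(
    panel: GenotypePanel,
    genpos: np.ndarray,
    window_cM: float = 3.0,
    impute_mean: bool = False,
) -> LDMatrix:
    """Sparse Pearson correlations within a strict genetic-distance window.

    ``R[j, k]`` is stored iff the variants share a chromosome and
    ``|genpos[j] - genpos[k]| < window_cM``.  Missing dosages are handled
    pairwise-complete by default, or mean-imputed per column when
    ``impute_mean`` is set.  Monomorphic columns get a unit diagonal and no
    off-diagonal entries.
    """
    X = panel.dosages
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 individuals to compute correlations")
    genpos = np.asarray(genpos, dtype=np.float64)
    chrom = panel.variants["chr"].to_numpy(str)

    has_missing = bool(np.isnan(X).any())
    if has_missing and impute_mean:
        X = X.copy()
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(col_mean, idx[1])
        has_missing = False

    if not has_missing:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        mono = sd == 0
        safe_sd = np.where(mono, 1.0, sd)
        Z = (X - mean) / safe_sd
    else:
        mono = panel.monomorphic()

    rows, cols, vals = [], [], []
    for c in np.unique(chrom):
        cidx = np.flatnonzero(chrom == c)
        g = genpos[cidx]
        if np.any(np.diff(g) < 0):
            raise ValueError(f"genetic positions not sorted within chromosome {c}")
        for a, j in enumerate(cidx):
            hi = a + np.searchsorted(g[a:], g[a] + window_cM, side="left")
            nbr = cidx[a + 1 : hi]
            if len(nbr) == 0 or mono[j]:
                continue
            nbr = nbr[~mono[nbr]]
            if len(nbr) == 0:
                continue
            if not has_missing:
                r = (Z[:, j] @ Z[:, nbr]) / (n - 1)
            else:
                r = np.array([_pairwise_corr(X[:, j], X[:, k]) for k in nbr])
            np.clip(r, -1.0, 1.0, out=r)
            rows.extend([j] * len(nbr))
            cols.extend(nbr)
            vals.extend(r)

    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    vals = np.asarray(vals, dtype=np.float64)
    upper = sp.coo_matrix((vals, (rows, cols)), shape=(m, m))
    R = (upper + upper.T + sp.eye(m, format="coo")).tocsr()
    return LDMatrix(
        R=R, genpos=genpos, variants=panel.variants.copy(), window_cM=window_cM,
        monomorphic=np.asarray(mono, dtype=bool),
    )


def ld_scores(ld: LDMatrix) -> np.ndarray:
    """LD scores: per-variant sum of squared stored correlations (incl. the diagonal)."""
    return np.asarray(ld.R.multiply(ld.R).sum(axis=1)).ravel()


def assemble_genomewide(blocks: list[LDMatrix]) -> LDMatrix:
    """Block-diagonal concatenation of per-chromosome LD matrices."""
    seen: set[str] = set()
    for b in blocks:
        chroms = set(b.variants["chr"].astype(str))
        if chroms & seen:
            raise ValueError(f"duplicated chromosome(s) across blocks: {sorted(chroms & seen)}")
        seen |= chroms
    R = sp.block_diag([b.R for b in blocks], format="csr")
    return LDMatrix(
        R=R,
        genpos=np.concatenate([b.genpos for b in blocks]),
        variants=pd.concat([b.variants for b in blocks], ignore_index=True),
        window_cM=max(b.window_cM for b in blocks),
        monomorphic=np.concatenate([b.monomorphic for b in blocks]),
    )
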