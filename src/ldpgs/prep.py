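"""Summary-statistics preparation: scaling, QC and heritability estimation.

Marginal GWAS effects gamma_hat on the allele-dosage scale are converted to
the standardized scale via beta_hat = gamma_hat / (se * sqrt(n)) (a Z-score
divided by sqrt(n)); the inverse factor se * sqrt(n) is kept per variant so
posterior means can be mapped back to the allele scale.  The QC filter
compares the genotype standard deviation implied by the summary statistics
(SD_ss) with the one observed in a validation panel (SD_val) and removes
variants where the two disagree.  SNP heritability is estimated by LD score
regression with the intercept constrained to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def effective_sample_size(ncase, ncontrol):
    """Effective sample size of a case-control GWAS: 4 / (1/ncase + 1/ncontrol).

    Equals the total sample size for a balanced design and tends to
    4 * min(ncase, ncontrol) under extreme imbalance.
    """
    ncase = np.asarray(ncase, dtype=np.float64)
    ncontrol = np.asarray(ncontrol, dtype=np.float64)
    if np.any(ncase <= 0) or np.any(ncontrol <= 0):
        raise ValueError("case and control counts must both be positive")
    out = 4.0 / (1.0 / ncase + 1.0 / ncontrol)
    return float(out) if out.ndim == 0 else out


@dataclass
class ScaledBetas:
    """Standardized-scale marginal effects with per-variant back-scaling."""

    beta_hat: np.ndarray  # gamma_hat / (se * sqrt(n))
    scale: np.ndarray  # se * sqrt(n); allele-scale effect = beta * scale
    n: np.ndarray  # per-variant (effective) sample size

    def __post_init__(self):
        self.beta_hat = np.asarray(self.beta_hat, dtype=np.float64)
        self.scale = np.asarray(self.scale, dtype=np.float64)
        self.n = np.asarray(self.n, dtype=np.float64)
        if not np.all(self.scale > 0):
            raise ValueError("back-scaling factors must be positive")

    def back_scale(self, omega: np.ndarray) -> np.ndarray:
        """Map standardized posterior means back to the allele scale."""
        return np.asarray(omega) * self.scale

    @property
    def m(self) -> int:
        return self.beta_hat.size


def scale_to_std(ss: pd.DataFrame) -> ScaledBetas:
    """Convert marginal allele-scale effects to the standardized scale."""
    se = ss["se_gamma"].to_numpy(np.float64)
    n = ss["n"].to_numpy(np.float64)
    scale = se * np.sqrt(n)
    return ScaledBetas(
        beta_hat=ss["gamma_hat"].to_numpy(np.float64) / scale, scale=scale, n=n
    )


def sd_from_sumstats(
    ss: pd.DataFrame,
    trait: str = "linear",
    sd_y: float | None = None,
    sd_val: np.ndarray | None = None,
    allow_min_rule: bool = True,
) -> np.ndarray:
    """Per-variant genotype SD implied by the summary statistics.

    Linear traits: SD_ss = sd(y) / (se * sqrt(n)); when sd(y) is unknown it
    is estimated by the median of sd_val * se * sqrt(n) if validation SDs
    are available, else (fallback) by min(0.5 * se * sqrt(n)), which uses
    the fact that SD_ss cannot exceed 0.5 for a 0/1-coded standardized
    trait.  Binary traits (n = effective sample size): SD_ss =
    2 / (se * sqrt(n_eff)).
    """
    se_sqrt_n = ss["se_gamma"].to_numpy(np.float64) * np.sqrt(ss["n"].to_numpy(np.float64))
    if trait == "binary":
        return 2.0 / se_sqrt_n
    if trait != "linear":
        raise ValueError(f"unknown trait type: {trait!r}")
    if sd_y is None:
        if sd_val is not None:
            sd_y = float(np.median(np.asarray(sd_val) * se_sqrt_n))
        elif allow_min_rule:
            sd_y = float(np.min(0.5 * se_sqrt_n))
        else:
            raise ValueError(
                "linear trait needs sd_y, validation SDs, or the min rule enabled"
            )
    return sd_y / se_sqrt_n


QC_RULES = ("sd_ss_lt_half_val", "sd_ss_gt_val_plus_0.1", "sd_ss_lt_0.1", "sd_val_lt_0.05")


@dataclass
class QcReport:
    sd_ss: np.ndarray
    sd_val: np.ndarray
    keep: np.ndarray
    rule_counts: dict = field(default_factory=dict)
    rule_flags: pd.DataFrame | None = None
    sd_y_est: float | None = None

    @property
    def n_removed(self) -> int:
        return int((~self.keep).sum())

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"sd_ss": self.sd_ss, "sd_val": self.sd_val, "keep": self.keep})
        if self.rule_flags is not None:
            out = pd.concat([out, self.rule_flags], axis=1)
        return out


def qc_filter(sd_ss: np.ndarray, sd_val: np.ndarray) -> QcReport:
    """Keep a variant iff none of the four SD-comparison rules fires.

    Removal rules (all strict): sd_ss < 0.5*sd_val; sd_ss > sd_val + 0.1;
    sd_ss < 0.1; sd_val < 0.05.
    """
    sd_ss = np.asarray(sd_ss, dtype=np.float64)
    sd_val = np.asarray(sd_val, dtype=np.float64)
    if sd_ss.shape != sd_val.shape:
        raise ValueError("sd_ss and sd_val must have the same length")
    flags = pd.DataFrame(
        {
            QC_RULES[0]: sd_ss < 0.5 * sd_val,
            QC_RULES[1]: sd_ss > sd_val + 0.1,
            QC_RULES[2]: sd_ss < 0.1,
            QC_RULES[3]: sd_val < 0.05,
        }
    )
    keep = ~flags.any(axis=1).to_numpy()
    return QcReport(
        sd_ss=sd_ss,
        sd_val=sd_val,
        keep=keep,
        rule_counts={r: int(flags[r].sum()) for r in QC_RULES},
        rule_flags=flags,
    )


def ldsc_h2_constrained(
    chi2: np.ndarray,
    ell: np.ndarray,
    n,
    M: int | None = None,
    n_passes: int = 2,
    clamp: tuple[float, float] = (1e-4, 1.0),
) -> float:
    """SNP heritability by LD score regression with the intercept fixed at 1.

    Fits chi2_j = 1 + n_j * h2 * ell_j / M by weighted least squares.  The
    first pass weights by 1/ell_j; subsequent passes add the standard
    heteroscedasticity factor 1/(1 + n_j*h2*ell_j/M)^2 using the previous
    estimate.  The result is clamped to ``clamp``.
    """
    chi2 = np.asarray(chi2, dtype=np.float64)
    ell = np.asarray(ell, dtype=np.float64)
    n = np.broadcast_to(np.asarray(n, dtype=np.float64), chi2.shape)
    if M is None:
        M = chi2.size
    if not np.any(ell != 0):
        raise ValueError("all LD scores are zero; cannot run LDSC")
    x = n * ell / M
    y = chi2 - 1.0
    w = 1.0 / np.maximum(ell, 1e-8)
    h2 = float(np.sum(w * x * y) / np.sum(w * x * x))
    for _ in range(n_passes - 1):
        h2c = min(max(h2, clamp[0]), clamp[1])
        w = 1.0 / (np.maximum(ell, 1e-8) * (1.0 + n * h2c * ell / M) ** 2)
        h2 = float(np.sum(w * x * y) / np.sum(w * x * x))
    return min(max(h2, clamp[0]), clamp[1])
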