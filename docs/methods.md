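# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator, and the limitations of `ldpgs`.

## From marginal to joint effects

For a genotype matrix G (n individuals × m variants) with per-variant
standard deviations S and a phenotype y with var(y) = 1, the marginal
(single-variant) OLS effects and the joint (all-variants) effects are
linked through the correlation matrix R:

    γ_joint = S⁻¹ R⁻¹ S γ_marg.

Because se(γ̂ⱼ) ≈ sd(y) / (sd(Gⱼ)·√n), the standardized marginal effect
can be formed from summary statistics alone as β̂ⱼ = γ̂ⱼ/(se(γ̂ⱼ)·√nⱼ)
(a Z-score divided by √n), and posterior means on the standardized scale
are mapped back to the allele scale by multiplying with se(γ̂ⱼ)·√nⱼ.
This back-scaling is exact whatever sd(y) is, because sd(y) cancels
between S⁻¹ and S; the package therefore never needs genotype SDs to
rescale output, only the per-variant (se, n) pairs.  Per-variant sample
sizes nⱼ are carried through every formula in place of a scalar n; M
always denotes the total variant count.

For case-control GWAS, n is the effective sample size
n_eff = 4/(1/n_case + 1/n_control), and the implied genotype SD becomes
2/(se·√n_eff).

## Gibbs sampler

One sweep visits every variant in ascending genomic order (fixed order
for determinism).  For variant j:

1. β̃ⱼ = β̂ⱼ − (Rβ)ⱼ + Rⱼⱼβⱼ, read from a cached R·β product that is
   updated incrementally along the stored column of each changed effect
   and recomputed from scratch every 100 sweeps (configurable) to bound
   floating-point drift;
2. the causal posterior probability is evaluated as
   p̄ⱼ = 1/(1 + ((1−p)/p)·√(1 + nⱼh²/(Mp))·exp(−½·nⱼβ̃ⱼ²/(1 + Mp/(nⱼh²)))).
   The exponent is never positive, so the expression cannot overflow for
   arbitrarily large nⱼβ̃ⱼ²; the equivalent two-Gaussian-density ratio is
   used only as a test oracle (in extended precision);
3. βⱼ is drawn from N(β̃ⱼ/(1+Mp/(nⱼh²)), (1/(1+Mp/(nⱼh²)))·(1/nⱼ)) with
   probability p̄ⱼ, else set to 0, and the per-sweep posterior mean is
   ωⱼ = p̄ⱼ·β̃ⱼ/(1+Mp/(nⱼh²)).  With the sparse rule active, p̄ⱼ < p sets
   both βⱼ and ωⱼ to exact zeros.

Posterior-mean effects Ω average ω over the post-burn-in sweeps.
Defaults are burn_in = 100, num_iter = 500 per grid model and
500 + 500 for auto chains; all are exposed.  The ratio Mp/(nh²) is capped
at 1e12 so the degenerate p → 0 / h² → 0 corner stays finite.  A chain is
flagged diverged when β̃ becomes non-finite or any |βⱼ| exceeds 10 on the
standardized scale (standardized effects of real traits are orders of
magnitude smaller).  The sampler kernel is compiled with numba; each
chain's RNG is seeded from a SeedSequence of (random_state, model index),
so grid and auto results are reproducible and independent of how chains
are scheduled across threads.

Note one property that is sometimes assumed but does **not** hold: the
per-variant posterior mean |ωⱼ| is not monotone in p at fixed β̃ⱼ.  For
large n the causal probability saturates at 1 while the slab shrinkage
weakens as p decreases, so |ωⱼ| can locally *increase* as p falls; only
the limit ω → 0 as p → 0 is guaranteed (and, for strong signals, is
reached only at astronomically small p).

## Infinitesimal model

At p = 1 the posterior mean solves (R + M/(n·h²)·I)β = β̂ with n the mean
per-variant sample size; the package uses a sparse direct factorization
and verifies the relative residual is below 1e-10.  The Gibbs sampler at
p = 1 converges to the same solution, which the tests check to within
Monte-Carlo error.

## Heritability by constrained LD-score regression

E[χ²ⱼ] = 1 + nⱼ·h²·ℓⱼ/M with ℓⱼ = Σₖ R²ⱼₖ over stored entries.  The fit
is weighted least squares with the intercept fixed at 1, iterated twice:
the first pass weights by 1/ℓⱼ, the second adds the standard
heteroscedasticity factor 1/(1 + nⱼh²ℓⱼ/M)² using the first-pass
estimate.  The estimate is clamped to [1e-4, 1]: the lower bound keeps
downstream grid multipliers positive, the upper is the liability-scale
ceiling.  Only the point estimate is produced (no block jackknife).

## Auto model

Between sweeps, p is redrawn from Beta(1 + M_c, 1 + M − M_c) where M_c
counts currently nonzero effects (uniform prior on p), and h² is set to
βᵀRβ.  Because the windowed R can be indefinite, the quadratic form is
floored at 1e-4 (flagged); a chain whose h² exceeds 1.5 for 10
consecutive updates is flagged diverged.  Thirty chains (default) start
from p log-spaced on [1e-4, 0.9] with the LDSC h² as the common h² start.
Final effects average the chains whose predictor SD lies within three
median absolute deviations of the median; the predictor SD is computed
on a reference genotype panel when one is supplied and otherwise from
the √(ΩᵀRΩ) proxy (the choice is recorded per chain).  Point estimates
p̂, ĥ² are the means of the post-burn-in trajectories of the kept
chains.  The sparse companion of the auto model is a single sparse grid
run at (p̂, ĥ²).  The sparse rule is never active inside auto chains
(it would bias M_c).

With few chains the auto model can occupy a metastable "everything
weakly causal" mode on data with very few causal variants; the MAD
filter exists precisely to discard such chains, and it needs enough
chains to establish a majority (the 30-chain default; tests use 6–10).

## Windowed LD

R stores Pearson correlations only for pairs on the same chromosome
strictly closer than `window_cM` centimorgans (3 cM default), using
genetic positions interpolated piecewise-linearly from a (bp, cM) map
with linear extrapolation beyond the terminal knots.  Genetic distance
is the right metric because recombination, not physical distance,
determines LD range: an 8 Mb long-range LD region can span only ~3 cM.
Missing dosages are handled pairwise-complete (mean imputation
available); monomorphic variants keep a unit diagonal, no off-diagonal
entries, and a flag.  Entries are clipped to [−1, 1].  No
positive-semidefinite projection is applied, so quadratic forms in the
windowed R may be slightly negative — downstream consumers floor them.
Strict inequality at exactly the window size is a fixed convention.
Per-chromosome blocks concatenate block-diagonally for genome-wide runs.

## Quality control of summary statistics

SD_ss (the genotype SD implied by the summary statistics) is compared
with SD_val (the SD observed in the validation panel); a variant is
removed when any of the four rules fires (all strict): SD_ss < 0.5·SD_val,
SD_ss > SD_val + 0.1, SD_ss < 0.1, SD_val < 0.05.  For linear traits with
unknown sd(y), the default estimator is the median of SD_val·se·√n over
variants (robust); the fallback, min(0.5·se·√n), uses the fact that a
0/1-coded unit-variance trait bounds SD_ss by 0.5.

## Synthetic data generator

Genotypes: each haplotype is a latent stationary AR(1) Gaussian process
along the chromosome (corr ρ^|j−k|, default ρ = 0.6) thresholded at the
normal quantile of the variant's allele frequency (uniform in
[0.05, 0.5]); dosage = sum of two independent haplotypes.  This yields
controllable, smoothly decaying local LD cheaply and reproducibly.  It
does **not** model recombination hotspots, allele-frequency/LD coupling,
population structure or relatedness, so passing tests demonstrate
correctness of the algorithms under the assumed model, not robustness to
those real-data features.  The emitted genetic map runs at ~1 cM/Mb with
an optional compressed segment (3/8 rate over the middle fifth)
emulating a long-range LD region.

Phenotypes follow the liability threshold model: causal variants drawn
uniformly (a fixed count, as in scenario tables), standardized-scale
weights N(0, h²/|S|), the genetic component rescaled so its in-sample
variance is *exactly* h², the Gaussian residual orthogonalized against
it and rescaled so the total in-sample variance is exactly 1, cases
above the (1 − prevalence) normal quantile.  GWAS output is per-variant
OLS with intercept for continuous traits (vectorized, missing dosages
excluded per variant) and per-variant logistic regression for binary
traits (statsmodels; non-converging variants dropped).

A second generator draws summary statistics directly from the
standardized-scale model, β̂ ~ N(Rβ, R/n) with exact AR(1) noise, for
tests that need the sampler's own assumptions to hold exactly; it
rescales β so βᵀRβ = h² exactly, the same exact-variance convention as
the phenotype simulator.  Default conditions for recovery checks:
M = 2000, n = 20 000, p = 0.02, h² = 0.3.

## Evaluation

AUC is the Mann–Whitney statistic (ties count ½); confidence intervals
come from bootstrapping individuals (10 000 replicates by default;
single-class replicates are redrawn so the count stays fixed).  Model
selection among candidate scores uses the absolute Z-score of the
phenotype-on-score simple linear regression (also for binary traits;
constant scores get Z = 0, ties resolve to the lowest index).  The
theoretical ceiling on AUC for a predictor equal to the true genetic
liability is the normal-theory closed form in (h², K) built from the
truncated-normal case/control liability means; it is an approximation
that agrees with direct simulation of the liability model to about
5·10⁻⁴ at h² = 0.3, K = 0.15.

## File formats

Summary statistics are whitespace/tab-delimited with a header and
canonical column names (mappable); chromosome labels are normalized by
stripping a `chr` prefix; positions are 1-based.  Genotypes use PLINK 1
bed/bim/fam with the standard 2-bit encoding; a dosage counts copies of
the bim's first-listed allele, which after matching is the effect
allele.  Matching is on (chr, pos): same-order alleles pass, swapped
alleles flip the effect sign, strand-ambiguous pairs (A/T, C/G) are
removed by default because strand cannot be resolved without
frequencies.  The LD container is a versioned npz bundle of the
symmetric CSR arrays at full double precision plus variant metadata and
the window size; round trips are bit-exact and a version-tag mismatch is
a hard error.

## Problem sizes used in tests

The test suite and recovery checks run at desk scale, chosen to exercise
every code path with tight statistical margins: auto-model recovery at
M = 2000 variants, n = 20 000 (10 chains × 10 seeds); the end-to-end
ordering check (tuned grid ≥ infinitesimal and > marginal scoring) at
m = 800, n = 8000 with an 18-model grid over 5 seeds; simulator
contracts at n = 50 000 individuals.  Biobank-scale runs (hundreds of
thousands of individuals × millions of variants) are out of scope for
the simulation harness, though the samplers themselves only ever touch
the sparse LD structure and scale linearly in stored entries.

## Known limitations

No BGEN/dosage input, multi-allelic variants or indels; no shrinkage or
r²-thresholded LD estimation; no functional-annotation priors,
multi-ancestry models, posterior standard errors, or formal convergence
diagnostics (the MAD filter is a pragmatic substitute); unconstrained
(free-intercept) LDSC is not provided.  The auto model inherits the
sensitivity to summary-statistics quality documented for this model
class — the QC filter should be run first.
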