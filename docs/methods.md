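# Methods

This note documents the statistical models implemented in `oxbspipe`, the
choices made where the design was genuinely open, and what passing the test
suite does and does not demonstrate.

## Paired-arm model of 5mC and 5hmC

Each CpG carries an unobserved methylation fraction m (5mC) and
hydroxymethylation fraction h (5hmC) with m + h ≤ 1. The bisulfite arm
measures m + h, the oxidative-bisulfite arm measures m, each with technical
noise. The estimator ĥ = β(BS) − β(oxBS) is unbiased but inherits noise
from both arms: with independent per-arm noise of sd σ the subtraction
noise is N(0, √2 σ), so truly unhydroxymethylated sites produce negative
values about half the time. The magnitudes of those negative values are a
direct sample of the noise distribution's absolute values, and their 95%
quantile (linear-interpolation definition, pooled over probes and samples)
is used as the detectability floor: probes whose across-sample mean ĥ falls
below it are discarded. This is a positive threshold on magnitudes —
taking the quantile of the signed negatives would give a near-zero value
with no screening power. Negative entries of surviving probes are retained
(not clipped) so the downstream linear model stays unbiased near zero; a
`clip_negatives` flag is available.

A pooled threshold is the default; a per-sample variant (median of
per-sample quantiles) is offered because the original procedure's pooling
is not recoverable from its description.

## Preprocessing

1. **Filtering**, in order, each probe attributed to the first rule that
   removes it: manifest blacklist (SNP control and cross-hybridizing
   probes); detection p > 0.05 in more than 1% of samples; bead count < 3
   in more than 5% of samples. Both arms are filtered to the identical set.
2. **Quantile normalization** within each arm separately: every sample's
   sorted values are replaced by the across-sample mean of sorted values.
   The arms are normalized independently because they measure different
   quantities. Within-probe-type normalization activates when the manifest
   provides a `probe_type` column; the synthetic data has no probe-type
   dimension, so plain full-quantile is the default.
3. **Batch adjustment** with parametric ComBat applied sequentially per
   categorical batch variable (chip, then position), protecting genotype:
   standardize per probe against a design containing batch and genotype,
   estimate per-batch location/scale on the standardized scale, shrink them
   toward across-probe priors (normal prior for locations, inverse-gamma
   for scales, hyperparameters by method of moments, posterior by the
   standard iterative solution), remove, and back-transform. Two deliberate
   numerical choices differ from the common reference implementation: the
   pooled variance uses the residual degrees of freedom (n − rank) rather
   than n, and per-batch scale estimates are normalized by the batch's
   share of the residual df. With these conventions, identically
   distributed batches give δ̂ = 1 exactly and the adjustment is a no-op on
   batch-homogeneous data (verified to 1e-8), which the naive ddof mix
   violates by O(1/n_batch). Continuous passage is removed by linear
   residualization on a genotype-protected design, the standard continuous
   analogue of categorical ComBat. Output is clipped to [0, 1].

## Moderated differential testing

Per probe, `β ~ genotype` is fit once with all genotype levels
(dummy-coded against the contrast's reference), so each non-reference
coefficient equals a group-mean difference; the effect Δβ is computed
directly as mean(group) − mean(reference) (identical to the coefficient,
exact on degenerate probes). The empirical-Bayes variance prior (d₀, s₀²)
comes from moment-matching the marginal distribution of log s² to a scaled
F (digamma/trigamma moment equations, trigamma inverted by Newton
iteration). Posterior variances s̃² = (d₀s₀² + d·s²)/(d₀ + d) give
t = Δβ/(s̃·√(cᵀ(XᵀX)⁻¹c)) on d₀ + d df (normal reference when d₀ = ∞). A
`prior_df` override supports d₀ = 0 (ordinary OLS t, used as a test oracle)
and d₀ = ∞. The implementation is cross-checked in the test suite against
the R/Bioconductor limma reference on a shared fixture (agreement to 1e-6
on t).

Hits require BH padj ≤ 0.05 **and** |Δβ| ≥ 0.05; the effect threshold sits
above the technical-replicate noise scale of EPIC arrays. Probes with any
missing value are excluded from modeling (complete-case). Direction
convention: group − reference, so a planted increase yields positive Δβ.

The skewness test uses the population coefficient g₁ = m₃/m₂^{3/2} with a
Monte-Carlo normal null (default 1000 simulations) and the +1-corrected
two-sided p, so the smallest reportable p is 1/(n_sim + 1); an adjusted
(bias-corrected) statistic is available by flag.

## Co-methylated regions

Probes are sorted by (chromosome, position); a probe joins the open run iff
its gap to the previous probe is ≤ 1 kb and its Pearson correlation with
the previous probe (pairwise-complete across samples) is ≥ 0.4; runs of
≥ 2 probes become CMRs. The consecutive-pair rule is the simplest reading
consistent with the stated parameters; the original package's
sliding-window variant is out of scope, and results are flagged as
consecutive-pair-based. Composites are convex combinations of member
betas, weights = |PC1 loadings| normalized to sum 1 (PC1 from the
column-centered member × sample matrix, sign-aligned to the cross-probe
mean); zero-variance regions fall back to the plain mean. Composites are
tested exactly like single probes, at the same thresholds.

## Permutation nulls

All four procedures resample uniformly without replacement from their
backgrounds at the observed set sizes, 10 000 iterations by default, fully
reproducible from a seed and invariant to input order (inputs are
canonicalized). Tail p-values count ties in both tails, which keeps
p > 0 and is conservative; literal strict counting ("more than / fewer
than") is available via `strict=True` with a numeric floor of 1/n_iter
(flagged `at_floor`). Tie-inclusive counting makes the p-value distribution
slightly super-uniform when the overlap statistic is very discrete; the
calibration tests therefore use configurations with large overlap variance
where the discreteness lumps are small.

## RRBS beta regression

After coverage filters (≥ 10× in all samples, ≤ the 99.9% pooled-coverage
quantile — note the quantile cap is relative to its input dataset, so it is
the one filter that is not a pure per-site predicate — covered in all
samples) and the between-group variability filter (|group mean ratio
difference| must exceed 0.10, matching the |Δβ| ≥ 0.1 hit threshold), each
cytosine's methylation ratios are fit by beta regression: logit link for
the mean, constant precision φ, maximum likelihood. Ratios touching 0 or 1
are shrunk by (y(n−1) + 0.5)/n; interior ratios are left untouched so the
shrinkage does not attenuate effects. The Wald statistic z = γ̂/se(γ̂) is
referred to a t distribution with n − 3 df (two mean parameters plus
precision): at RRBS group sizes (n = 4 vs 4) the asymptotic normal
reference is badly liberal (empirical type-I ≈ 0.14 at nominal 0.05),
while the t reference keeps it ≈ 0.07 — the small-sample liberality that
remains is documented here and bounded in the tests. Non-convergent fits
are flagged with missing p and excluded from BH, never fatal.

## Multi-omic integration

Region assignment: promoter = within ±1 kb of a TSS of the gene; enhancer
= inside a ±5 kb-padded H3K4me1 peak that also lies within the gene's
±5 kb-padded span (the attribution rule is not printed anywhere
authoritative; span-proximity is the choice here); body = inside the span
and not promoter. Multi-assignment across genes and region types is
allowed.

Within a (gene, region, modification), CpG p-values combine by signed,
significance-weighted Stouffer: zᵢ = Φ⁻¹(1 − pᵢ/2)·sign(Δβᵢ), weights
wᵢ = |Δβᵢ| (equal when all zero), z = Σwz/√Σw², p = 2(1 − Φ(|z|)). Across
components (six region × modification slots plus expression) the same
weighted combination runs on unsigned z, because methylation and
expression sign conventions are not commensurable; weights default to
{expression 0.4; enhancer 5mC 0.125; promoter 5mC 0.125; body 5mC 0.1;
enhancer 5hmC 0.125; promoter 5hmC 0.125; body 5hmC 0.1} renormalized over
present components, with equal-weight and modality-heavy alternatives
accepted via config. Two caveats are deliberate and documented rather than
patched: (i) the printed weight vector sums to 1.1, not 1 — renormalization
makes the combination invariant to that scale; (ii) combining two-sided
p-values through unsigned z is anticonservative under the global null
(e.g. seven components all at p = 0.5 combine to ≈ 0.01, not 0.5), which
is inherent to direction-free combination and shared by the approach this
reimplements; gene scores are therefore rankings, not calibrated p-values.
Fisher's method (X² = −2Σln p on 2k df) combines category p-values across
comparisons.

Module search runs spin-glass (simulated-annealing modularity) community
detection on each connected component of the interaction network that
contains at least one candidate gene (score p ≤ 0.05), with unscored nodes
set to a neutral p = 0.5. The search deliberately runs on full components
rather than a candidate-induced subgraph: induction distorts the degrees
entering the modularity null model and empirically halves planted-module
recovery. Module score = mean(−log₁₀ p) over members; the empirical module
p compares that score against random permutations of the score labels on
the fixed topology (default 100), because the method reports module ranks
rather than calibrated significance. The annealing consumes Python's
`random` state, seeded per call, so results are deterministic given the
seed.

ORA is the hypergeometric upper tail on hit/background gene sets with BH
across sets, set sizes restricted to [5, 500] after intersection with the
background. Probes map to genes by the longest annotated transcript, ties
broken lexicographically; intergenic probes stay unmapped.

## Synthetic data

The generator emulates the statistical structure of the three-genotype
design: 7/8/8 samples; bimodal beta-distributed methylation; hmC near zero
for most probes and 0.08–0.30 for a 30% subset, capped at 1 − mC; planted
genotype effects applied on the logit scale and sized to realize the
requested beta-scale change at the probe's baseline (so effects shrink at
the boundaries instead of clipping); more and larger 5mC effects in the
first transgenic group than the second, and predominantly positive 5hmC
effects, mirroring the study's qualitative signature; correlated CpG
blocks (2–5 probes, gaps 100–800 bp, between-block gaps > 2 kb) driven by
a shared per-sample latent factor (loading 0.06 against total noise sd
≈ 0.022, giving consecutive-pair r ≈ 0.88); a 20% subset of blocks carries
a region-wide planted effect; chip and row offsets (sd 0.01/0.005);
shared-then-independent technical noise (per-cell baseline sd 0.01 common
to both arms plus per-arm sd 0.02, chosen to match the ~2% technical
replicate RMSE reported for EPIC data) so negative subtraction values
arise exactly as in real paired-arm data; sparse QC failures (0.05% of
cells, reproducing a ≈1% detection-filter loss at 23 samples); and 0.5%
blacklisted probes. RRBS counts use negative-binomial depths (mean 30,
size 5) and binomial methylated reads with logit-scale effects.

What it does **not** emulate: Illumina type-I/type-II probe chemistry and
dye bias, read-level conversion errors, cell-composition heterogeneity,
genome-scale probe density and its correlation structure beyond the
planted blocks, and realistic gene/transcript geometry. Passing tests
therefore demonstrate that the procedures are implemented correctly and
behave as designed under their stated noise model — not that they are
robust to every artifact of real array or sequencing data.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 12 000 probes
for the end-to-end pipeline, 10⁴ probes for null calibrations, 50 seeds ×
400 probes for CMR recovery, 500 cytosines for beta-regression recovery,
200 runs for permutation-uniformity checks, 200-node networks (50 seeds)
for module recovery. These sizes give Monte-Carlo error comfortably inside
the stated tolerances; all quantities are recomputed at run time from the
seed.

## Known limitations

- The moderated model supports a single categorical covariate (genotype);
  additional covariates belong in preprocessing (residualization).
- The CMR chaining rule is consecutive-pair only; no external-reference
  panels.
- Beta regression uses constant precision across groups.
- Gene scores are rankings (see the anticonservativeness note above).
- The depth-quantile RRBS filter is input-relative and thus not
  idempotent at the extreme tail.
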