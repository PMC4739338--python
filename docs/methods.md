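# Methods

## The model

`regionvc` partitions the phenotypic variance of a quantitative trait
across classes of genomic regions using kernel (RKHS/GBLUP) regression.
Phenotypes are assumed pre-adjusted for systematic effects, so the model
for `n` genotyped individuals is

    y = 1 mu + sum_t g_t + e,        g_t ~ N(0, K_t sigma2_t),
                                     e   ~ N(0, I sigma2_e),

where each `K_t` is a genomic relationship matrix built from one set of
SNPs.  Three configurations cover the analyses the package supports:

1. a single additive kernel `G` (whole genome, or one region at a time);
2. `G + D`, adding a dominance kernel for the same SNP set;
3. six additive kernels `G_1 ... G_6` fitted jointly, one per annotation
   class: intergenic, intron, missense, synonymous, UTR (5' and 3'
   merged), and "up-down" (5 kb gene flanks).

The additive kernel uses centered, standardized dosages
(`z_j = (x_j - 2 p_j) / sqrt(2 p_j q_j)`, `G = Z Z' / m`), so
`mean(diag(G)) ~ 1` and `sigma2_t` is on the scale of phenotypic
variance.  The dominance kernel uses the orthogonal dominance coding
(dosage 0, 1, 2 mapped to `-2p^2, 2pq, -2q^2`, with `p` the frequency of
the counted allele) standardized by `4 sum p_j^2 q_j^2`.  At exact
Hardy–Weinberg proportions this coding is mean-zero and orthogonal to
the centered additive code at every SNP, which is what makes an
additive/dominance decomposition meaningful.  (Some descriptions of this
coding swap the roles of `p` and `q`; the assignment used here is the
one that satisfies those two identities, with the large-magnitude code
on the rare homozygote.)

Genomic ("marked") heritability for kernel `t` is reported as the
posterior mean of the per-draw ratio `sigma2_t / (sum_k sigma2_k +
sigma2_e)`, so the fractions and the residual fraction sum to one in
every draw.

## Gibbs sampler

Priors are a flat prior on `mu` and independent scaled inverse-chi-square
priors on all variances with `df = 5`.  The prior scale is set so the
prior mode of each kernel variance is `var(y) * R2 / n_kernels` and the
residual prior mode is `var(y) * (1 - R2)`, with `R2 = 0.5` by default.

Sampling is performed in the eigenbasis of each kernel: `K_t = U L U'`
is decomposed once (eigenvalues below `1e-10 * max` truncated, which also
removes the null direction created by column centering), `g_t = U gamma_t`
is updated through the independent scalar full conditionals of
`gamma_t`, and `sigma2_t` is drawn from a scaled inverse-chi-square with
`df + rank(K_t)` degrees of freedom and quadratic form
`gamma_t' L^-1 gamma_t` (the pseudo-inverse form `g' K^- g`).  Rank is
used rather than `n` because the kernels are rank-deficient after
centering (and per-region kernels with few SNPs are strongly so).  One
`O(n^3)` decomposition per kernel buys `O(n * rank)` per iteration,
which keeps six-kernel chains tractable on one core.

Draws are consumed in a fixed order (intercept, each kernel's `gamma` in
input order, each kernel variance, residual variance), so runs are
bit-reproducible given a seed.  The default desk chain is 20 000
iterations / 2 000 burn-in / thin 10 (1 800 retained draws); the long
reference chain (500 000 / 50 000 / 50, 9 000 retained draws) is
available as `REFERENCE_CHAIN` for final inference.  Convergence is
monitored programmatically: autocorrelation-based effective sample size
(Geyer initial-positive-sequence truncation) and a Geweke-style
first-10 % / last-50 % mean-difference z-score per variance component.

The sampler was validated two ways: with variances fixed, the posterior
mean of `g` matches the closed-form ridge/GBLUP solution
`G (G + lambda I)^-1 (y - ybar)` to correlation > 0.999; with variances
sampled, the posterior mean of h² matches an exact two-dimensional grid
integration of the single-kernel posterior to three decimals.

### Behavior worth knowing about

The posterior mean of a *weakly identified* variance component under a
scaled inverse-chi-square prior sits above the likelihood peak (the
prior is heavy-tailed and the posterior is right-skewed).  At desk scale
(n = 800, m = 4 000, six kernels at realistic chip proportions — the
smallest class has ~20 SNPs) this is visible: fitting six kernels to a
pure-noise phenotype leaves each component near h² ~ 0.04 instead of 0,
and with real signal the six-kernel total overshoots the truth by
roughly that margin, while the single-kernel whole-genome fit at the
same n is accurate.  This is a property of the model and priors, not of
the sampler (see the grid-integration check above); it shrinks as n and
the per-kernel SNP counts grow, and it is the reason the per-region sum
should always be read against the whole-genome single-kernel estimate.
Degenerate input: a constant phenotype drives all variance components
toward zero; the heritability ratio is then a ratio of vanishing
quantities and is reported but not meaningful.

## Prediction and cross-validation

Genetic values for held-out individuals are predicted by the
multivariate-normal conditional expectation
`ghat_test = K_ts (K_tt)^-1 ghat_train`, with a jittered Cholesky solve
(`eps = 1e-8 * mean diag`) and pseudo-inverse fallback; kernels are built
once from the full sample (train + test) and blocks are subset, so allele
frequencies come from the full panel.  Predicted phenotypes are
`mu + sum_t ghat_t,test`.  Cross-validation uses random fourfold splits
replicated (15 replicates by default); within a replicate the four test
folds' predictions are concatenated before computing the Pearson
correlation and MSE, which is more stable than per-fold correlations at
a few hundred test individuals.  Zero-variance predictions yield a
missing correlation (never 0) plus a warning.  Per-fold refits use a
short chain (3 000 / 500 / 5 by default) since only posterior means of
`g` enter the prediction.

## Quality control and annotation

SNP filters follow dense-chip practice: missing rate > 0.05, MAF < 0.01,
and Hardy–Weinberg chi-square p < 1e-6 (one degree of freedom, no
continuity correction; monomorphic SNPs return p = 1 by convention).
MAF and HWE are computed on non-missing calls before imputation; the
report stores the first failing rule in the order missingness → MAF →
HWE, though the surviving set does not depend on that order.  Remaining
missing calls are mean-imputed, which contributes exactly zero to
centered additive relationship entries for imputed cells.

Annotation consumes a VEP-style consequence table.  Multi-consequence
SNPs collapse to one class by severity precedence missense >
synonymous > UTR > intron > up-down > intergenic (the six classes must
be disjoint; the precedence is this package's documented rule, mirroring
VEP severity convention).  SNPs absent from the table are discarded, not
silently classed.  A coordinate-based helper derives 5 kb gene-flank
membership from gene intervals (0-based half-open) when only gene
coordinates are available.

## Synthetic data generator

The generator emulates the data regime of a dense 600K-chip study of a
closed commercial broiler line, at reduced scale:

- **LD and relatedness.** A pool of 40 founder haplotypes is drawn from
  a latent-Gaussian AR(1) model (per-3 kb-step correlation 0.995,
  shared-variance plateau 0.89); sample haplotypes are first-order
  Markov mosaics of the pool (switch probability 0.002 per SNP).
  Founder thresholds are placed at empirical quantiles so every SNP is
  polymorphic in the pool at close to its drawn MAF.  These defaults
  were calibrated once so that mean dosage r² is ~0.32 for pairs < 20 kb
  apart, decaying to ~0.21 at 100 kb, and they produce a spread of
  genomic relationships (off-diagonal SD ~ 0.22) typical of a closed
  breeding line.  Relatedness matters: without it, kernel variances are
  nearly confounded with the residual and estimates follow the prior.
- **MAF.** Uniform on (0.04, 0.5), mean ~0.27.
- **Region classes.** Largest-remainder apportionment at the SNP-count
  shares of a ~310k post-QC chicken panel (intergenic 44.9 %, intron
  40.1 %, missense 0.5 %, synonymous 1.8 %, UTR 1.0 %, up-down 11.7 %),
  placed randomly along the genome by default, or contiguously
  ("blocked") to concentrate each class at one locus.
- **Architecture.** Per-region additive effects i.i.d. normal on the
  standardized codes (default 0.05 of phenotypic variance per region,
  total 0.30), a dominance component on the Vitezica codes (default
  0.05), Gaussian residual.  Each component is orthogonalized against
  the ones placed before it and rescaled, so realized variance fractions
  are *exact* in every replicate — recovery tests compare against exact
  ground truth, and the generating process matches the model's
  cross-kernel independence assumption.  `mu = 0` by default.

What the generator does not emulate: multi-chromosome genomes,
coalescent-exact LD, selection, explicit pedigrees, sex chromosomes,
non-Gaussian residuals, genotyping error.  Passing recovery tests
therefore demonstrate correctness of the machinery under a faithful but
idealized population model, not performance guarantees on real broiler
data.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at n = 800 / m = 4 000 (recovery and sum
consistency), n = 600 / m = 2 400 (blocked separate-vs-joint inflation),
and n = 360 / m = 720–1 200 (cross-validation calibration), with the
20 000-iteration desk chain for variance estimation and shorter chains
inside CV folds.  These sizes were chosen so the entire pipeline runs
comfortably on a single core while keeping every qualitative contrast
(inflation, sum consistency, null calibration, heritability ordering)
well resolved.

## Known limitations

- Six-kernel posterior means carry the small-sample upward drift
  described above; report them alongside the whole-genome fit.
- The additive/dominance split is only as identifiable as the kernels
  are distinct; element-wise correlations between `G` and `D` around
  0.7–0.8 (as on real chips) mean part of the dominance estimate is
  additive signal relabeled.  The package reports what the model
  attributes; interpretation needs the same caution as the analyses it
  reimplements.
- The 12-kernel joint additive + dominance model (six of each) is out of
  scope, as are REML estimation, LD-aware imputation, and binary PLINK
  parsing.
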