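# regionvc

Partitioning the genetic variance of quantitative traits across classes
of genomic regions — intergenic, intron, missense, synonymous, UTR, and
5 kb gene flanks ("up-down") — with multi-kernel Bayesian RKHS/GBLUP
regression, and scoring each partition's predictive ability by
cross-validation.

The scientific question: how much of the marked (SNP-captured) additive
and dominance variation of a complex trait is attributable to each
functional class of the genome, and does any class predict unobserved
phenotypes better than the whole genome?  The package implements the
full pipeline used to answer this in dense-chip livestock data — SNP
quality control, annotation-based partitioning, per-region genomic
relationship matrices, Gibbs-sampled variance components, and
replicated fourfold cross-validation — plus a synthetic-data generator
with exact ground truth, aimed at quantitative geneticists and method
developers who want a transparent, testable reference implementation.

## Model

For pre-adjusted phenotypes `y` on `n` genotyped individuals,

    y = 1μ + Σ_t g_t + e,   g_t ~ N(0, K_t σ²_t),   e ~ N(0, I σ²_e)

with kernels `K_t` chosen per analysis:

- **G** — additive genomic relationships from centered, standardized
  dosages, `G = ZZ'/m` (whole genome or one region);
- **G + D** — adding the dominance kernel,
  `D = X_D X_D' / (4 Σ p²q²)` with the orthogonal dominance coding
  `(-2p², 2pq, -2q²)` for dosages (0, 1, 2);
- **G₁ + … + G₆** — six additive kernels fitted jointly, one per
  annotation class.

Priors: flat on μ, scaled inverse-χ² (df = 5) on every variance with the
prior mode split as `var(y)·R²/n_kernels` per kernel (R² = 0.5).  The
Gibbs sampler works in each kernel's eigenbasis (one decomposition per
kernel, O(n·rank) per iteration).  Genomic heritability per kernel is
the posterior mean of the per-draw ratio `σ²_t / (Σ σ²_k + σ²_e)`.
Held-out genetic values are predicted by the conditional expectation
`ĝ_test = K_test,train K_train⁻¹ ĝ_train` and scored by Pearson
correlation and MSE under 4-fold CV with 15 random replicates.

See `docs/methods.md` for the full model description, numerical choices
and known limitations.

## Worked example

Simulate a panel with a known architecture (six region classes at
realistic chip proportions, additive h² = 0.30 split equally, dominance
0.05), build kernels, and estimate the variance components:

```python
import numpy as np
from regionvc import (
    ChainSpec, ModelSpec, SyntheticConfig, assign_regions,
    build_additive_kernel, build_dominance_kernel, fit_multikernel,
    simulate_genotypes, simulate_phenotypes, summarize,
)

cfg = SyntheticConfig(n_individuals=800, n_snps=4000, seed=1)
geno = simulate_genotypes(cfg)
annot = assign_regions(geno.snp_ids, cfg.region_proportions, seed=1)
y, truth = simulate_phenotypes(geno, annot, cfg)
print(truth.variance_fractions["additive_total"],
      truth.variance_fractions["dominance"])   # 0.30, 0.05 (exact)

G = build_additive_kernel(geno)
D = build_dominance_kernel(geno)
fit = fit_multikernel(y, ModelSpec(kernels=[G, D],
                                   chain=ChainSpec(20_000, 2_000, 10),
                                   seed=1))
est = summarize(fit)
print(est.table.round(3))
```

Output from this exact script:

```
0.3 0.04999999999999999
  component  var_mean  var_sd  h2_mean  h2_sd
0     A_all     0.312   0.061    0.294  0.046
1     D_all     0.126   0.033    0.119  0.030
2  residual     0.620   0.046    0.587  0.049
```

Reading the numbers: the additive kernel is credited with h² ≈ 0.29
(truth 0.30) and the dominance kernel with ≈ 0.12 (truth 0.05) — the
dominance estimate runs high because `G` and `D` built from the same
SNPs are far from orthogonal (element-wise correlation ≈ 0.7–0.8), so
the two-kernel split leans on the prior; the additive estimate and the
ordering (dominance ≪ additive) are reliable.  The same mechanics drive
the separate-vs-joint contrast: fitting one region's kernel alone
absorbs, through LD, signal that belongs to the rest of the genome, so
separate per-region estimates sum to far more than the whole-genome
heritability, while the joint six-kernel partition stays near it.

The same pipeline is available from the shell:

```bash
regionvc simulate --n-individuals 800 --n-snps 4000 --seed 1 --out run/sim
regionvc qc run/sim.ped --out run/qc
regionvc kernels run/qc.dosages.tsv --annotation run/sim.annotation.tsv \
    --dominance --out run/kernels
regionvc fit run/sim.pheno.tsv run/kernels/A_all.kernel.tsv --out run/fit
regionvc cv  run/sim.pheno.tsv run/kernels/A_all.kernel.tsv --out run/cv
regionvc distances run/kernels/*.kernel.tsv --out run/distances.tsv
```

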