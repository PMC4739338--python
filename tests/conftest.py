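import numpy as np
import pytest

from regionvc import (
    SyntheticConfig,
    assign_regions,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_panel():
    """A small LD-structured panel with phenotypes and ground truth."""
    cfg = SyntheticConfig(n_individuals=300, n_snps=600, seed=42)
    geno = simulate_genotypes(cfg)
    annot = assign_regions(geno.snp_ids, cfg.region_proportions, seed=42)
    y, truth = simulate_phenotypes(geno, annot, cfg)
    return cfg, geno, annot, y, truth


@pytest.fixture(scope="session")
def hwe_panel():
    """Independent SNPs in exact-expectation HWE (no LD, large n)."""
    cfg = SyntheticConfig(
        n_individuals=500,
        n_snps=400,
        ld_decay_rho=0.0,
        ld_background=0.0,
        seed=7,
    )
    return simulate_genotypes(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
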