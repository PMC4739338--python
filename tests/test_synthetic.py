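"""Synthetic genotype/phenotype generator: LD, apportionment, ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from regionvc import (
    CHIP_REGION_COUNTS,
    InvalidConfigError,
    SyntheticConfig,
    assign_regions,
    ld_summary,
    simulate_genotypes,
    simulate_phenotypes,
)
from regionvc.synthetic import apportion_counts

from .test_qc import make_geno

TABLE_TOTAL = sum(CHIP_REGION_COUNTS.values())


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_individuals=1),
            dict(n_snps=1),
            dict(maf_range=(0.0, 0.5)),
            dict(maf_range=(0.3, 0.1)),
            dict(ld_decay_rho=1.0),
            dict(region_proportions={"intron": 0.7}),
            dict(region_additive_h2={"intron": 0.7, "intergenic": 0.31}),
            dict(dominance_h2=-0.01),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(**kwargs)


class TestGenotypes:
    def test_same_seed_is_bit_identical(self):
        cfg = SyntheticConfig(n_individuals=60, n_snps=120, seed=5)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.snp_ids == b.snp_ids

    def test_dosages_are_biallelic_counts(self, small_panel):
        _, geno, _, _, _ = small_panel
        assert set(np.unique(geno.dosages)) <= {0.0, 1.0, 2.0}

    def test_independent_snps_have_null_level_r2(self):
        # no AR structure, no founder pool: r2 ~ E under independence = 1/(n-1)
        cfg = SyntheticConfig(
            n_individuals=250,
            n_snps=300,
            ld_decay_rho=0.0,
            ld_background=0.0,
            n_founder_haplotypes=None,
            seed=1,
        )
        geno = simulate_genotypes(cfg)
        table = ld_summary(geno, bin_edges_bp=[0, 10**9])
        assert table.mean_r2.iloc[0] == pytest.approx(1 / 249, abs=2e-3)

    def test_extreme_rho_matches_two_locus_oracle(self):
        # adjacent latent correlation 0.999 at equal MAF: dosage r2 should
        # approach the bivariate-normal two-locus haplotype-frequency value
        maf = 0.3
        cfg = SyntheticConfig(
            n_individuals=600,
            n_snps=40,
            maf_range=(maf, maf),
            ld_decay_rho=0.999,
            ld_background=1.0,
            n_founder_haplotypes=None,
            seed=2,
        )
        geno = simulate_genotypes(cfg)
        Z = (geno.dosages - geno.dosages.mean(0)) / geno.dosages.std(0)
        r2 = np.mean(
            [(Z[:, j] @ Z[:, j + 1] / len(Z)) ** 2 for j in range(39)]
        )
        t = stats.norm.ppf(maf)
        p11 = stats.multivariate_normal.cdf([t, t], mean=[0, 0], cov=[[1, 0.999], [0.999, 1]])
        d = p11 - maf**2
        oracle = d**2 / (maf * (1 - maf)) ** 2
        assert r2 > 0.9
        assert r2 == pytest.approx(oracle, abs=0.05)

    def test_realized_maf_mean_tracks_config(self, small_panel):
        _, geno, _, _, _ = small_panel
        p = geno.dosages.mean(axis=0) / 2
        maf = np.minimum(p, 1 - p)
        assert maf.mean() == pytest.approx(0.27, abs=0.02)


class TestAssignRegions:
    def test_chip_proportions_reproduce_chip_counts(self):
        proportions = {k: v / TABLE_TOTAL for k, v in CHIP_REGION_COUNTS.items()}
        counts = apportion_counts(proportions, TABLE_TOTAL)
        assert counts == CHIP_REGION_COUNTS

    def test_single_class_takes_all(self):
        annot = assign_regions(100, {"intron": 1.0}, seed=0)
        assert (annot.classes == "intron").all()

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            assign_regions(10, {"exotic": 1.0}, seed=0)

    @given(
        n=st.integers(2, 500),
        weights=st.lists(st.integers(1, 50), min_size=2, max_size=6),
        seed=st.integers(0, 99),
    )
    @settings(max_examples=80, deadline=None)
    def test_apportionment_conserves_total(self, n, weights, seed):
        labels = ["intergenic", "intron", "missense", "synonymous", "UTR", "up-down"]
        total_w = sum(weights)
        proportions = {
            lab: w / total_w for lab, w in zip(labels, weights)
        }
        annot = assign_regions(n, proportions, seed=seed)
        counts = annot.counts()
        assert counts.sum() == n
        for lab, frac in proportions.items():
            assert abs(counts[lab] - frac * n) <= 1  # within rounding

    def test_blocked_mode_is_contiguous(self):
        annot = assign_regions(90, {"intron": 1 / 3, "UTR": 1 / 3, "up-down": 1 / 3},
                               seed=0, mode="blocked")
        labels = annot.classes.to_numpy()
        changes = (labels[1:] != labels[:-1]).sum()
        assert changes == 2  # exactly one boundary between consecutive blocks


class TestPhenotypes:
    def test_decomposition_identity_exact(self, small_panel):
        _, _, _, y, truth = small_panel
        np.testing.assert_allclose(truth.phenotype(), y, rtol=0, atol=1e-12)

    def test_zero_architecture_gives_pure_noise(self):
        cfg = SyntheticConfig(
            n_individuals=100,
            n_snps=60,
            region_additive_h2={"intron": 0.0},
            region_proportions={"intron": 1.0},
            dominance_h2=0.0,
            seed=3,
        )
        geno = simulate_genotypes(cfg)
        annot = assign_regions(geno.snp_ids, cfg.region_proportions, seed=3)
        y, truth = simulate_phenotypes(geno, annot, cfg)
        assert np.var(sum(truth.g.values())) == 0.0
        np.testing.assert_allclose(y, cfg.mu + truth.e)

    def test_realized_fractions_are_exact(self, small_panel):
        # components are orthogonalized before scaling, so every realized
        # fraction equals its target exactly (the generator's ground-truth
        # guarantee), regardless of LD between regions
        _, _, _, y, truth = small_panel
        for region in ("intron", "intergenic", "up-down", "missense"):
            assert truth.variance_fractions[region] == pytest.approx(0.05, abs=1e-9)
        assert truth.variance_fractions["dominance"] == pytest.approx(0.05, abs=1e-9)
        assert truth.variance_fractions["additive_total"] == pytest.approx(
            0.30, abs=1e-9
        )
        # and the reported fractions agree with direct recomputation
        vary = np.var(y)
        assert np.var(truth.d) / vary == pytest.approx(
            truth.variance_fractions["dominance"], rel=1e-12
        )

    def test_components_are_mutually_orthogonal(self, small_panel):
        _, _, _, _, truth = small_panel
        parts = list(truth.g.values()) + [truth.d, truth.e]
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                cov = np.cov(parts[i], parts[j])[0, 1]
                assert abs(cov) < 1e-9

    def test_overcommitted_variance_rejected(self, small_panel):
        cfg, geno, annot, _, _ = small_panel
        bad = SyntheticConfig(
            n_individuals=cfg.n_individuals, n_snps=cfg.n_snps, seed=cfg.seed
        )
        bad.region_additive_h2 = {"intron": 0.6}
        bad.dominance_h2 = 0.5  # bypasses __post_init__; the operation re-checks
        with pytest.raises(ValueError, match="sum"):
            simulate_phenotypes(geno, annot, bad)


class TestLDSummary:
    def test_duplicated_snp_has_r2_one(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.4, size=120).astype(float)
        geno = make_geno(np.column_stack([col, col]))
        geno.positions[:] = [1000, 1000]
        table = ld_summary(geno, bin_edges_bp=[0, 10, 1000])
        assert table.mean_r2.iloc[0] == pytest.approx(1.0)

    def test_monomorphic_columns_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        X = np.column_stack(
            [rng.binomial(2, 0.4, 100), np.zeros(100), rng.binomial(2, 0.3, 100)]
        ).astype(float)
        geno = make_geno(X)
        with pytest.warns(UserWarning, match="monomorphic"):
            table = ld_summary(geno, bin_edges_bp=[0, 10_000])
        assert table.n_pairs.iloc[0] == 1  # only the two polymorphic SNPs pair up

    def test_empty_bin_reported_as_missing(self):
        rng = np.random.default_rng(2)
        X = rng.binomial(2, 0.4, size=(80, 2)).astype(float)
        geno = make_geno(X)  # positions 1000 and 2000
        table = ld_summary(geno, bin_edges_bp=[0, 500, 5000])
        assert np.isnan(table.mean_r2.iloc[0])
        assert table.n_pairs.iloc[0] == 0

    def test_decay_is_monotone_on_average(self):
        r2 = np.zeros(3)
        for seed in range(3):
            cfg = SyntheticConfig(n_individuals=300, n_snps=500, seed=seed)
            table = ld_summary(
                simulate_genotypes(cfg), bin_edges_bp=[0, 20_000, 60_000, 150_000]
            )
            r2 += table.mean_r2.to_numpy()
        r2 /= 3
        assert r2[0] >= r2[1] >= r2[2]

    def test_calibration_matches_target_ld_profile(self):
        # generator defaults against the two calibration levels:
        # ~0.32 below 20 kb and ~0.21 around 100 kb
        short, long_ = [], []
        for seed in range(3):
            cfg = SyntheticConfig(n_individuals=500, n_snps=700, seed=seed)
            t = ld_summary(
                simulate_genotypes(cfg), bin_edges_bp=[0, 20_000, 95_000, 105_000]
            )
            short.append(t.mean_r2.iloc[0])
            long_.append(t.mean_r2.iloc[2])
        assert np.mean(short) == pytest.approx(0.32, abs=0.05)
        assert np.mean(long_) == pytest.approx(0.21, abs=0.05)
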