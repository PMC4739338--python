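"""Additive/dominance relationship matrices, kernel distances, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regionvc import (
    SyntheticConfig,
    assign_regions,
    build_additive_kernel,
    build_dominance_kernel,
    cluster_kernels,
    kernel_distance,
    kernel_distance_matrix,
    simulate_genotypes,
    subset_kernel,
)
from regionvc.annotation import iter_region_snp_indices
from regionvc.data import KernelMatrix
from regionvc.kernels import (
    MonomorphicSNPError,
    additive_codes,
    dominance_codes,
    elementwise_correlation,
)

from .test_qc import make_geno


class TestAdditiveKernel:
    def test_single_snp_hand_computed(self):
        # dosages (0, 2), p = 0.5: Z = (-sqrt2, +sqrt2), G = ZZ'/1
        geno = make_geno(np.array([[0.0], [2.0]]))
        G = build_additive_kernel(geno)
        np.testing.assert_allclose(G.values, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-12)

    def test_identical_individuals_give_constant_matrix(self):
        row = np.array([0.0, 1.0, 2.0, 1.0])
        geno = make_geno(np.tile(row, (4, 1)))
        # frequencies must come from a polymorphic reference: supply them
        G = build_additive_kernel(geno, freqs=np.full(4, 0.4))
        assert np.ptp(G.values) == pytest.approx(0.0, abs=1e-12)

    def test_mean_diagonal_near_one_under_hwe(self, hwe_panel):
        G = build_additive_kernel(hwe_panel)
        assert np.diag(G.values).mean() == pytest.approx(1.0, abs=0.05)

    def test_symmetric_and_psd(self, small_panel):
        _, geno, _, _, _ = small_panel
        G = build_additive_kernel(geno)
        np.testing.assert_allclose(G.values, G.values.T, atol=1e-10)
        assert G.is_psd()

    def test_column_order_invariance(self, small_panel):
        _, geno, _, _, _ = small_panel
        perm = np.random.default_rng(0).permutation(geno.n_snps)
        G1 = build_additive_kernel(geno)
        G2 = build_additive_kernel(geno.subset_snps(perm))
        np.testing.assert_allclose(G1.values, G2.values, atol=1e-10)

    def test_duplicating_every_snp_leaves_g_unchanged(self, small_panel):
        _, geno, _, _, _ = small_panel
        doubled = geno.subset_snps(list(range(geno.n_snps)) * 2)
        G1 = build_additive_kernel(geno)
        G2 = build_additive_kernel(doubled)
        np.testing.assert_allclose(G1.values, G2.values, atol=1e-10)

    def test_monomorphic_snp_rejected(self):
        geno = make_geno(np.array([[0.0, 0.0], [2.0, 0.0]]))
        with pytest.raises(MonomorphicSNPError):
            build_additive_kernel(geno)


class TestDominanceKernel:
    def test_codes_at_half(self):
        codes = dominance_codes(np.array([0.0, 1.0, 2.0]), np.full(3, 0.5))
        np.testing.assert_allclose(codes, [-0.5, 0.5, -0.5], atol=1e-12)

    def test_codes_at_p09(self):
        # counted-allele frequency 0.9: the rare homozygote carries the
        # large-magnitude code so the coding stays mean-zero under HWE
        codes = dominance_codes(np.array([0.0, 1.0, 2.0]), np.full(3, 0.9))
        np.testing.assert_allclose(codes, [-1.62, 0.18, -0.02], atol=1e-12)

    def test_single_snp_hand_computed(self):
        # individuals (aa, Aa) at p = 0.5: X_D = (-0.5, 0.5),
        # D = X_D X_D' / (4 * 0.0625)
        geno = make_geno(np.array([[0.0], [1.0]]))
        D = build_dominance_kernel(geno, freqs=np.array([0.5]))
        np.testing.assert_allclose(D.values, [[1.0, -1.0], [-1.0, 1.0]], atol=1e-12)

    @given(p=st.floats(0.01, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_additive_dominance_orthogonality_at_hwe(self, p):
        """Frequency-weighted inner product of the codes is 0 at exact HWE."""
        q = 1.0 - p
        freqs = np.array([q * q, 2 * p * q, p * p])  # genotype proportions
        x = np.array([0.0, 1.0, 2.0])
        add = x - 2 * p
        dom = dominance_codes(x, np.full(3, p))
        assert abs(np.sum(freqs * add * dom)) < 1e-12
        assert abs(np.sum(freqs * dom)) < 1e-12  # mean-zero as well

    def test_psd_on_panel(self, small_panel):
        _, geno, _, _, _ = small_panel
        D = build_dominance_kernel(geno)
        assert D.is_psd()
        assert D.kind == "dominance"


class TestSubset:
    def test_full_subset_is_identity(self, small_panel):
        _, geno, _, _, _ = small_panel
        G = build_additive_kernel(geno)
        block = subset_kernel(G, G.sample_ids, G.sample_ids)
        np.testing.assert_array_equal(block, G.values)

    def test_principal_submatrix_stays_psd(self, small_panel):
        _, geno, _, _, _ = small_panel
        G = build_additive_kernel(geno)
        ids = G.sample_ids[10:60]
        block = subset_kernel(G, ids, ids)
        assert np.linalg.eigvalsh(block).min() > -1e-8 * np.linalg.eigvalsh(
            block
        ).max()

    def test_unknown_id_raises(self, small_panel):
        _, geno, _, _, _ = small_panel
        G = build_additive_kernel(geno)
        with pytest.raises(KeyError):
            subset_kernel(G, ["not-a-sample"], G.sample_ids[:2])


def _kernel(values, ids=None, **kw):
    n = len(values)
    return KernelMatrix(
        sample_ids=ids or [f"s{i}" for i in range(n)], values=np.asarray(values), **kw
    )


class TestKernelDistance:
    def test_identical_kernels_distance_zero(self):
        K = _kernel(np.eye(3))
        assert kernel_distance(K, K) == 0.0

    def test_identity_vs_zero(self):
        assert kernel_distance(_kernel(np.eye(2)), _kernel(np.zeros((2, 2)))) == (
            pytest.approx(np.sqrt(2.0))
        )

    def test_matches_elementwise_brute_force(self, rng):
        A = rng.standard_normal((6, 6))
        B = rng.standard_normal((6, 6))
        Ka = _kernel(A + A.T)
        Kb = _kernel(B + B.T)
        brute = np.sqrt(sum(
            (Ka.values[i, j] - Kb.values[i, j]) ** 2
            for i in range(6)
            for j in range(6)
        ))
        assert kernel_distance(Ka, Kb) == pytest.approx(brute, abs=1e-12)

    def test_id_mismatch_raises(self):
        Ka = _kernel(np.eye(2), ids=["a", "b"])
        Kb = _kernel(np.eye(2), ids=["b", "a"])
        with pytest.raises(ValueError, match="sample ids"):
            kernel_distance(Ka, Kb)


class TestClustering:
    def test_closest_pair_merges_first(self):
        D = np.array([[0, 0.1, 10], [0.1, 0, 10], [10, 10, 0]], dtype=float)
        Z, order = cluster_kernels(["k1", "k2", "k3"], D)
        assert sorted(Z[0, :2].astype(int)) == [0, 1]  # k1, k2 merge first
        assert set(order) == {"k1", "k2", "k3"}

    def test_equal_distances_give_equal_heights(self):
        D = np.ones((3, 3)) - np.eye(3)
        Z, _ = cluster_kernels(["a", "b", "c"], D)
        assert np.allclose(Z[:, 2], 1.0)

    def test_non_finite_distance_rejected(self):
        D = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError, match="finite"):
            cluster_kernels(["a", "b"], D)


@pytest.fixture(scope="module")
def region_kernels():
    # regions interleaved along the genome (as on a real chip), each
    # with enough SNPs to average over many founder segments
    cfg = SyntheticConfig(n_individuals=250, n_snps=1800, seed=9)
    geno = simulate_genotypes(cfg)
    annot = assign_regions(
        geno.snp_ids,
        {label: 1 / 6 for label in cfg.region_proportions},
        seed=9,
        mode="random",
    )
    adds, doms = [], []
    for region, idx in iter_region_snp_indices(annot, geno):
        adds.append(build_additive_kernel(geno, idx, region=region))
        doms.append(build_dominance_kernel(geno, idx, region=region))
    return adds, doms


class TestRegionKernelStructure:
    def test_per_region_g_elements_highly_correlated(self, region_kernels):
        """Shared LD and relatedness make per-region G matrices carry
        near-identical relationship information."""
        adds, _ = region_kernels
        cors = [
            elementwise_correlation(adds[i], adds[j])
            for i in range(len(adds))
            for j in range(i + 1, len(adds))
        ]
        assert min(cors) > 0.8

    def test_additive_kernels_cluster_away_from_dominance(self, region_kernels):
        adds, doms = region_kernels
        within = [
            kernel_distance(adds[i], adds[j])
            for i in range(len(adds))
            for j in range(i + 1, len(adds))
        ]
        across = [kernel_distance(a, d) for a in adds for d in doms]
        assert np.mean(within) < np.mean(across)
        labels, D = kernel_distance_matrix(adds + doms)
        _, order = cluster_kernels(labels, D)
        assert len(order) == 12
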