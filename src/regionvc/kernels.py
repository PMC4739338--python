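"""Additive and dominance genomic relationship matrices and kernel comparison.

The additive kernel follows the centered-and-standardized construction
(VanRaden/Yang): each dosage column is centered by twice the allele
frequency and divided by its binomial standard deviation, and
``G = Z Z' / m``.  The dominance kernel uses the orthogonal dominance
coding of Vitezica et al.: genotypes (aa, Aa, AA) carrying dosages
(0, 1, 2) of the counted allele A with frequency p receive covariates
(-2p^2, 2pq, -2q^2), and ``D = X_D X_D' / (4 sum p_j^2 q_j^2)``.  Under
exact Hardy-Weinberg proportions this coding has mean zero and is
orthogonal to the centered additive code at every SNP, which is the
property that lets additive and dominance variance be separated.

Kernels are compared by the Euclidean (Frobenius) distance over all
``n^2`` corresponding elements and clustered by average linkage.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data import GenotypeMatrix, KernelMatrix


class MonomorphicSNPError(ValueError):
    """A kernel subset contains a SNP with no variation."""


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Counted-allele frequency per SNP, from the full supplied sample."""
    X = geno.dosages
    return np.nanmean(X, axis=0) / 2.0


def _check_polymorphic(freqs: np.ndarray, snp_ids: Sequence[str]) -> None:
    bad = np.flatnonzero((freqs <= 0.0) | (freqs >= 1.0))
    if bad.size:
        names = [snp_ids[i] for i in bad[:5]]
        raise MonomorphicSNPError(
            f"monomorphic SNPs must be filtered before kernel construction: {names}"
        )


def additive_codes(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Centered, standardized dosage matrix Z with columns (x - 2p)/sqrt(2pq)."""
    p = np.asarray(freqs, dtype=float)
    return (dosages - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def dominance_codes(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Vitezica dominance covariates for (possibly fractional) dosages.

    For integer dosages (0, 1, 2) the codes are (-2p^2, 2pq, -2q^2).
    Fractional (mean-imputed) dosages are handled by quadratic
    interpolation through those three points, via genotype-indicator
    weights ``I_aa = (1-x)(2-x)/2``, ``I_Aa = x(2-x)``,
    ``I_AA = x(x-1)/2``.
    """
    x = np.asarray(dosages, dtype=float)
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    i_aa = (1.0 - x) * (2.0 - x) / 2.0
    i_het = x * (2.0 - x)
    i_hom = x * (x - 1.0) / 2.0
    return i_aa * (-2.0 * p * p) + i_het * (2.0 * p * q) + i_hom * (-2.0 * q * q)


def build_additive_kernel(
    geno: GenotypeMatrix,
    snp_indices: Sequence[int] | np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    region: str = "all",
    standardize: bool = True,
) -> KernelMatrix:
    """Additive genomic relationship matrix G = ZZ'/m on a SNP subset.

    Frequencies default to estimates from the full supplied sample (so a
    total G can be built once and train/test blocks subset from it).
    ``standardize=False`` switches to the unstandardized VanRaden variant
    ``G = W W' / (2 sum p_j q_j)`` with W = X - 2p.
    """
    idx = (
        np.arange(geno.n_snps)
        if snp_indices is None
        else np.asarray(snp_indices, dtype=int)
    )
    if idx.size == 0:
        raise ValueError("empty SNP subset")
    X = geno.dosages[:, idx]
    if np.isnan(X).any():
        raise ValueError("genotypes must be imputed before kernel construction")
    p = allele_frequencies(geno) if freqs is None else np.asarray(freqs, dtype=float)
    p = p[idx] if freqs is None or len(p) == geno.n_snps else p
    snp_names = [geno.snp_ids[i] for i in idx]
    _check_polymorphic(p, snp_names)
    if standardize:
        Z = additive_codes(X, p)
        G = Z @ Z.T / idx.size
    else:
        W = X - 2.0 * p
        G = W @ W.T / (2.0 * np.sum(p * (1.0 - p)))
    G = (G + G.T) / 2.0
    return KernelMatrix(
        sample_ids=list(geno.sample_ids),
        values=G,
        kind="additive",
        region=region,
        n_snps_used=int(idx.size),
    )


def build_dominance_kernel(
    geno: GenotypeMatrix,
    snp_indices: Sequence[int] | np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    region: str = "all",
) -> KernelMatrix:
    """Dominance relationship matrix D = X_D X_D' / (4 sum p^2 q^2)."""
    idx = (
        np.arange(geno.n_snps)
        if snp_indices is None
        else np.asarray(snp_indices, dtype=int)
    )
    if idx.size == 0:
        raise ValueError("empty SNP subset")
    X = geno.dosages[:, idx]
    if np.isnan(X).any():
        raise ValueError("genotypes must be imputed before kernel construction")
    p = allele_frequencies(geno) if freqs is None else np.asarray(freqs, dtype=float)
    p = p[idx] if freqs is None or len(p) == geno.n_snps else p
    snp_names = [geno.snp_ids[i] for i in idx]
    _check_polymorphic(p, snp_names)
    q = 1.0 - p
    denom = 4.0 * np.sum(p * p * q * q)
    if denom <= 0.0:
        raise MonomorphicSNPError("dominance standardization constant is zero")
    XD = dominance_codes(X, p)
    D = XD @ XD.T / denom
    D = (D + D.T) / 2.0
    return KernelMatrix(
        sample_ids=list(geno.sample_ids),
        values=D,
        kind="dominance",
        region=region,
        n_snps_used=int(idx.size),
    )


def subset_kernel(
    K: KernelMatrix, row_ids: Sequence[str], col_ids: Sequence[str]
) -> np.ndarray:
    """Rectangular block of K for the requested row/column sample ids."""
    rows = K.sample_index(row_ids)
    cols = K.sample_index(col_ids)
    return K.values[np.ix_(rows, cols)]


def kernel_distance(Ka: KernelMatrix, Kb: KernelMatrix) -> float:
    """Euclidean distance over all n^2 corresponding kernel elements."""
    if Ka.sample_ids != Kb.sample_ids:
        raise ValueError("kernels must share the same sample ids in the same order")
    diff = Ka.values - Kb.values
    return float(np.sqrt(np.sum(diff * diff)))


def kernel_distance_matrix(
    kernels: Sequence[KernelMatrix],
) -> tuple[list[str], np.ndarray]:
    """Pairwise Euclidean distances between kernels; labels are kernel names."""
    labels = [K.name for K in kernels]
    n = len(kernels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kernel_distance(kernels[i], kernels[j])
    return labels, D


def cluster_kernels(
    labels: Sequence[str], distances: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering of a kernel distance matrix.

    Returns the scipy linkage matrix and the dendrogram leaf order as
    labels.  Ties are resolved deterministically by input (label) order,
    which scipy's condensed-distance convention guarantees.
    """
    distances = np.asarray(distances, dtype=float)
    if not np.isfinite(distances).all():
        raise ValueError("non-finite kernel distances")
    if distances.shape[0] != len(labels):
        raise ValueError("label/distance size mismatch")
    condensed = squareform(distances, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    order = hierarchy.leaves_list(Z)
    return Z, [labels[i] for i in order]


def elementwise_correlation(Ka: KernelMatrix, Kb: KernelMatrix) -> float:
    """Pearson correlation between corresponding elements of two kernels."""
    if Ka.sample_ids != Kb.sample_ids:
        raise ValueError("kernels must share the same sample ids in the same order")
    a = Ka.values.ravel()
    b = Kb.values.ravel()
    return float(np.corrcoef(a, b)[0, 1])


def plot_kernel_heatmap(
    labels: Sequence[str], distances: np.ndarray, path: str
) -> None:
    """Write a clustered heat-map of kernel distances to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _, order = cluster_kernels(labels, distances)
    idx = [list(labels).index(l) for l in order]
    M = distances[np.ix_(idx, idx)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(M, cmap="Reds_r")
    ax.set_xticks(range(len(order)), order, rotation=90)
    ax.set_yticks(range(len(order)), order)
    fig.colorbar(im, ax=ax, label="Euclidean distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
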