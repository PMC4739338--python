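"""Core in-memory containers shared by all pipeline stages.

Genotypes are held as an ``n_samples x n_snps`` allele-dosage matrix
(0/1/2 counts of the reference-counted allele, ``NaN`` for missing calls),
annotations as a SNP -> region-class mapping restricted to the six disjoint
classes, and relationship matrices as symmetric kernels tagged with their
kind (additive or dominance) and the region they were built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The six disjoint genomic-region classes, ordered by annotation precedence
#: (most severe consequence first; intergenic is the catch-all).
REGION_CLASSES: tuple[str, ...] = (
    "missense",
    "synonymous",
    "UTR",
    "intron",
    "up-down",
    "intergenic",
)


class InvalidConfigError(ValueError):
    """Raised when a configuration object fails validation."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-dosage matrix with positional metadata.

    Parameters
    ----------
    sample_ids : list of str
        One id per row of ``dosages``.
    snp_ids : list of str
        One id per column of ``dosages``.
    chromosomes : ndarray of str
        Chromosome label per SNP.
    positions : ndarray of int
        Base-pair position per SNP.
    dosages : ndarray, shape (n_samples, n_snps)
        Allele counts in {0, 1, 2}; ``NaN`` marks a missing call.  After
        mean imputation entries may be real-valued.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chromosomes = np.asarray(self.chromosomes)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if not (len(self.snp_ids) == len(self.positions) == len(self.chromosomes) == m):
            raise ValueError("snp_ids/positions/chromosomes do not match dosage columns")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where a call is missing."""
        return np.isnan(self.dosages)

    def subset_snps(self, indices: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given SNP column indices."""
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[i] for i in idx],
            chromosomes=self.chromosomes[idx],
            positions=self.positions[idx],
            dosages=self.dosages[:, idx],
        )

    def subset_samples(self, indices: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            chromosomes=self.chromosomes,
            snp_ids=list(self.snp_ids),
            positions=self.positions,
            dosages=self.dosages[idx, :],
        )

    def snp_indices(self, snp_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from exc


@dataclass
class RegionAnnotation:
    """Mapping of SNP id to one of the six disjoint region classes."""

    classes: pd.Series  # index: snp_id, values: class label

    def __post_init__(self) -> None:
        bad = set(self.classes.unique()) - set(REGION_CLASSES)
        if bad:
            raise ValueError(f"unknown region classes: {sorted(bad)}")
        if self.classes.index.has_duplicates:
            raise ValueError("duplicate SNP ids in annotation")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "RegionAnnotation":
        return cls(pd.Series(dict(mapping), dtype=object))

    def __len__(self) -> int:
        return len(self.classes)

    def label_of(self, snp_id: str) -> str:
        return self.classes.loc[snp_id]

    def snps_in(self, region: str) -> list[str]:
        if region not in REGION_CLASSES:
            raise ValueError(f"unknown region class {region!r}")
        return list(self.classes.index[self.classes == region])

    def counts(self) -> pd.Series:
        """SNP count per class, in canonical class order (zeros included)."""
        c = self.classes.value_counts()
        return c.reindex(REGION_CLASSES, fill_value=0)


@dataclass
class KernelMatrix:
    """Symmetric positive semi-definite relationship matrix.

    ``kind`` distinguishes additive (VanRaden/Yang standardized dosage)
    from dominance (Vitezica-coded) kernels; ``region`` records which
    annotation class the SNP subset came from ("all" for the whole panel).
    """

    sample_ids: list[str]
    values: np.ndarray
    kind: str = "additive"
    region: str = "all"
    n_snps_used: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape does not match sample ids")
        if self.kind not in ("additive", "dominance"):
            raise ValueError(f"kind must be additive|dominance, got {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kernel is not symmetric to 1e-10")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def name(self) -> str:
        prefix = "A" if self.kind == "additive" else "D"
        return f"{prefix}_{self.region}"

    def is_psd(self, rtol: float = 1e-8) -> bool:
        """Numerical PSD check: eigenvalues >= -rtol * max eigenvalue."""
        w = np.linalg.eigvalsh(self.values)
        return bool(w.min() >= -rtol * max(w.max(), 1.0))

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample id {exc.args[0]!r} not in kernel") from exc


@dataclass
class TrueComponents:
    """Ground-truth decomposition of a simulated phenotype.

    The identity ``phenotype = mu + sum_t g[t] + d + e`` holds exactly,
    element-wise, which gives recovery tests an exact target.
    """

    mu: float
    g: dict[str, np.ndarray]  # region -> length-n additive genetic values
    d: np.ndarray  # dominance values
    e: np.ndarray  # residuals
    variance_fractions: dict[str, float] = field(default_factory=dict)

    def phenotype(self) -> np.ndarray:
        total = self.mu + self.d + self.e
        for vec in self.g.values():
            total = total + vec
        return total
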