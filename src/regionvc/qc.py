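"""SNP quality control: MAF, Hardy-Weinberg and missingness filters.

Filters mirror standard panel editing for dense SNP chips: SNPs with a
minor allele frequency below 0.01, a Hardy-Weinberg chi-square p-value
below 1e-6, or a per-SNP missing rate above 0.05 are removed.  Remaining
missing calls are replaced by the SNP's mean observed dosage, which makes
the matrix complete while contributing zero to centered relationship
entries for the imputed cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix


class EmptyPanelError(ValueError):
    """No SNP survived filtering."""


@dataclass
class QCReport:
    """Per-SNP QC metrics and pass/fail status.

    ``table`` has one row per input SNP with columns ``snp_id``, ``maf``,
    ``hwe_p``, ``missing_rate``, ``passed`` and ``reason`` (the first
    failing rule in the order missingness -> maf -> hwe, empty string for
    retained SNPs).  Each excluded SNP carries exactly one primary reason.
    """

    table: pd.DataFrame

    def summary(self) -> pd.Series:
        excluded = self.table.loc[~self.table["passed"], "reason"]
        counts = excluded.value_counts()
        counts["retained"] = int(self.table["passed"].sum())
        return counts


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from one SNP's dosage vector.

    Computed over non-missing calls as ``min(p, 1 - p)`` where
    ``p = mean(dosage) / 2``.
    """
    x = np.asarray(dosages, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size == 0:
        raise ValueError("MAF undefined: all calls missing")
    p = obs.mean() / 2.0
    return float(min(p, 1.0 - p))


def hwe_test(n_aa: int, n_het: int, n_hom: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-square).

    Observed genotype counts ``(n_aa, n_het, n_hom)`` for dosage classes
    (0, 1, 2) are compared against expected counts ``(n q^2, 2 n p q,
    n p^2)`` under the allele frequency estimated from the same counts.
    No continuity correction.  A monomorphic SNP matches its expectation
    exactly and returns p = 1 by convention.
    """
    counts = np.array([n_aa, n_het, n_hom], dtype=float)
    if (counts < 0).any():
        raise ValueError("negative genotype count")
    n = counts.sum()
    if n == 0:
        raise ValueError("HWE test needs at least one genotype")
    p = (2 * counts[2] + counts[1]) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    q = 1.0 - p
    expected = n * np.array([q * q, 2 * p * q, p * p])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    # 3 classes - 1 - 1 estimated allele frequency = 1 df
    return float(stats.chi2.sf(chi2, df=1))


def _per_snp_metrics(geno: GenotypeMatrix) -> pd.DataFrame:
    X = geno.dosages
    n = X.shape[0]
    missing = np.isnan(X)
    missing_rate = missing.mean(axis=0)
    rows = []
    for j in range(X.shape[1]):
        obs = X[~missing[:, j], j]
        if obs.size == 0:
            rows.append((np.nan, np.nan))
            continue
        p = obs.mean() / 2.0
        maf = min(p, 1.0 - p)
        counts = (
            int((obs == 0).sum()),
            int((obs == 1).sum()),
            int((obs == 2).sum()),
        )
        rows.append((maf, hwe_test(*counts)))
    metrics = pd.DataFrame(rows, columns=["maf", "hwe_p"])
    metrics.insert(0, "snp_id", geno.snp_ids)
    metrics["missing_rate"] = missing_rate
    return metrics


def filter_snps(
    geno: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
    max_missing: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the missingness, MAF and HWE filters; order preserved.

    MAF and the HWE test are computed on non-missing calls, before any
    imputation.  The report records the first failing rule per SNP in the
    order missingness -> maf -> hwe (the surviving set does not depend on
    this order).

    Raises
    ------
    EmptyPanelError
        If no SNP survives.
    """
    metrics = _per_snp_metrics(geno)
    reason = np.full(len(metrics), "", dtype=object)
    fail_missing = metrics["missing_rate"].to_numpy() > max_missing
    all_missing = metrics["maf"].isna().to_numpy()
    fail_maf = (metrics["maf"].to_numpy() < maf_min) | all_missing
    fail_hwe = metrics["hwe_p"].fillna(0.0).to_numpy() < hwe_alpha
    reason[fail_hwe] = "hwe"
    reason[fail_maf] = "maf"
    reason[fail_missing] = "missing"
    passed = reason == ""
    report = QCReport(
        metrics.assign(passed=passed, reason=reason)
    )
    keep = np.flatnonzero(passed)
    if keep.size == 0:
        raise EmptyPanelError("no SNP survived QC filtering")
    return geno.subset_snps(keep), report


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the SNP's mean observed dosage."""
    X = geno.dosages.copy()
    missing = np.isnan(X)
    if not missing.any():
        return GenotypeMatrix(
            sample_ids=list(geno.sample_ids),
            snp_ids=list(geno.snp_ids),
            chromosomes=geno.chromosomes.copy(),
            positions=geno.positions.copy(),
            dosages=X,
        )
    n_obs = (~missing).sum(axis=0)
    if (n_obs == 0).any():
        bad = [geno.snp_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"all-missing SNPs cannot be imputed: {bad[:5]}")
    with np.errstate(invalid="ignore"):
        col_means = np.nansum(X, axis=0) / n_obs
    jj = np.nonzero(missing)
    X[jj] = col_means[jj[1]]
    return GenotypeMatrix(
        sample_ids=list(geno.sample_ids),
        snp_ids=list(geno.snp_ids),
        chromosomes=geno.chromosomes.copy(),
        positions=geno.positions.copy(),
        dosages=X,
    )
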