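"""Map SNPs to six disjoint genomic-region classes from consequence terms.

A VEP-style consequence table (snp_id -> one or more consequence terms)
is collapsed to a single class per SNP using a fixed severity precedence:
missense > synonymous > UTR > intron > up-down > intergenic.  5' and 3'
UTR consequences merge into one UTR class; upstream/downstream (5 kb
flank) consequences merge into "up-down".  SNPs absent from the table are
returned as discarded, mirroring panels where part of the chip cannot be
matched to the annotation database.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import REGION_CLASSES, GenotypeMatrix, RegionAnnotation
from .qc import compute_maf

#: VEP-style consequence term -> region class.
CONSEQUENCE_TO_CLASS: dict[str, str] = {
    "missense_variant": "missense",
    "start_lost": "missense",
    "stop_gained": "missense",
    "stop_lost": "missense",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
    "5_prime_UTR_variant": "UTR",
    "3_prime_UTR_variant": "UTR",
    "intron_variant": "intron",
    "splice_region_variant": "intron",
    "upstream_gene_variant": "up-down",
    "downstream_gene_variant": "up-down",
    "intergenic_variant": "intergenic",
}

#: Lower index = higher precedence when a SNP has several consequences.
_PRECEDENCE = {label: rank for rank, label in enumerate(REGION_CLASSES)}


class UnknownConsequenceError(ValueError):
    """A consequence term is outside the documented vocabulary."""


def classify_snps(
    consequences: pd.DataFrame,
    snp_ids: Sequence[str],
    on_unknown: str = "intergenic",
) -> tuple[RegionAnnotation, list[str]]:
    """Assign each panel SNP its single highest-precedence region class.

    Parameters
    ----------
    consequences : DataFrame
        Columns ``snp_id`` and ``consequence``; the consequence cell may
        hold several comma-separated terms, and a SNP may span several
        rows.
    snp_ids : sequence of str
        The SNP panel to classify.
    on_unknown : {"intergenic", "error"}
        Whether an out-of-vocabulary term maps to intergenic (with a
        warning) or raises :class:`UnknownConsequenceError`.

    Returns
    -------
    (RegionAnnotation, list of str)
        The annotation for matched SNPs and the ids of panel SNPs absent
        from the table (discarded, not classed).
    """
    if on_unknown not in ("intergenic", "error"):
        raise ValueError("on_unknown must be 'intergenic' or 'error'")
    required = {"snp_id", "consequence"}
    if not required.issubset(consequences.columns):
        raise ValueError(f"consequence table needs columns {sorted(required)}")

    best: dict[str, int] = {}
    unknown_terms: set[str] = set()
    for snp_id, cell in zip(consequences["snp_id"], consequences["consequence"]):
        for term in str(cell).split(","):
            term = term.strip()
            if not term:
                continue
            label = CONSEQUENCE_TO_CLASS.get(term)
            if label is None:
                if on_unknown == "error":
                    raise UnknownConsequenceError(
                        f"unknown consequence term {term!r} for SNP {snp_id!r}"
                    )
                unknown_terms.add(term)
                label = "intergenic"
            rank = _PRECEDENCE[label]
            prev = best.get(snp_id)
            if prev is None or rank < prev:
                best[snp_id] = rank
    if unknown_terms:
        warnings.warn(
            f"unknown consequence terms mapped to intergenic: {sorted(unknown_terms)}",
            stacklevel=2,
        )

    labels: dict[str, str] = {}
    discarded: list[str] = []
    for snp in snp_ids:
        if snp in best:
            labels[snp] = REGION_CLASSES[best[snp]]
        else:
            discarded.append(snp)
    annot = RegionAnnotation(pd.Series(labels, dtype=object))
    return annot, discarded


def updown_from_genes(
    chromosomes: np.ndarray,
    positions: np.ndarray,
    genes: pd.DataFrame,
    flank_bp: int = 5000,
) -> np.ndarray:
    """Coordinate-based membership in the 5 kb gene-flank ("up-down") class.

    ``genes`` holds 0-based half-open intervals (columns ``chrom``,
    ``start``, ``end``).  A SNP belongs to the flank class when it lies
    outside every gene body but within ``flank_bp`` of the nearest gene
    boundary on its chromosome.
    """
    chromosomes = np.asarray(chromosomes)
    positions = np.asarray(positions, dtype=np.int64)
    result = np.zeros(len(positions), dtype=bool)
    for chrom, sub in genes.groupby("chrom"):
        on_chrom = np.flatnonzero(chromosomes == chrom)
        if on_chrom.size == 0:
            continue
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        for i in on_chrom:
            pos = positions[i]
            inside = bool(((starts <= pos) & (pos < ends)).any())
            if inside:
                continue
            dist = np.minimum(np.abs(starts - pos), np.abs(pos - (ends - 1)))
            result[i] = bool((dist <= flank_bp).any())
    return result


def region_summary(annot: RegionAnnotation, geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-class SNP counts with mean and SD of MAF, plus an all-markers row.

    The annotation must cover every SNP in the panel; counts sum to the
    panel size.
    """
    missing = [s for s in geno.snp_ids if s not in annot.classes.index]
    if missing:
        raise ValueError(
            f"annotation does not cover the panel ({len(missing)} unclassified SNPs)"
        )
    mafs = np.array([compute_maf(geno.dosages[:, j]) for j in range(geno.n_snps)])
    labels = annot.classes.loc[geno.snp_ids].to_numpy()
    rows = []
    for label in REGION_CLASSES:
        sel = labels == label
        rows.append(
            {
                "region": label,
                "n_snps": int(sel.sum()),
                "mean_maf": float(mafs[sel].mean()) if sel.any() else np.nan,
                "sd_maf": float(mafs[sel].std(ddof=0)) if sel.any() else np.nan,
            }
        )
    rows.append(
        {
            "region": "all markers",
            "n_snps": int(len(labels)),
            "mean_maf": float(mafs.mean()),
            "sd_maf": float(mafs.std(ddof=0)),
        }
    )
    return pd.DataFrame(rows)


def iter_region_snp_indices(
    annot: RegionAnnotation, geno: GenotypeMatrix
) -> Iterable[tuple[str, np.ndarray]]:
    """Yield (region label, SNP column indices) for non-empty classes."""
    labels = annot.classes.loc[geno.snp_ids].to_numpy()
    for label in REGION_CLASSES:
        idx = np.flatnonzero(labels == label)
        if idx.size:
            yield label, idx
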