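"""Readers and writers for the plain-text interchange formats.

Genotypes travel either as PLINK text PED/MAP (white-space separated,
two allele columns per SNP, ``0 0`` for missing) or as a TSV dosage
matrix with a header row of SNP ids and a ``sample_id`` first column.
PED alleles are recoded to dosages against the minor allele.  Kernels,
QC reports, annotations and phenotypes are TSV; the simulated ground
truth is a JSON sidecar used by tests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, KernelMatrix, RegionAnnotation, TrueComponents

_MISSING_DOSAGE = "NA"


def write_ped_map(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write `prefix`.ped and `prefix`.map; dosage counts allele "B"."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for chrom, snp, pos in zip(geno.chromosomes, geno.snp_ids, geno.positions):
            fh.write(f"{chrom}\t{snp}\t0\t{pos}\n")
    allele_pairs = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sample in enumerate(geno.sample_ids):
            fields = [sample, sample, "0", "0", "0", "-9"]
            for x in geno.dosages[i]:
                if np.isnan(x):
                    fields.append("0 0")
                else:
                    if x not in allele_pairs:
                        raise ValueError(
                            "PED output requires integer dosages; write the TSV "
                            "dosage format for imputed (fractional) genotypes"
                        )
                    fields.append(allele_pairs[x])
            fh.write(" ".join(fields) + "\n")


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP, recoding alleles to minor-allele dosage.

    At each SNP the rarer allele is counted (ties broken toward the
    lexicographically larger allele, so fully heterozygous SNPs decode
    deterministically); ``0`` marks a missing allele.
    """
    prefix = Path(prefix)
    mp = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str},
    )
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    m = len(mp)
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"PED row has {len(parts)} fields, expected {6 + 2 * m}"
                )
            sample_ids.append(parts[1])
            rows.append(np.array(parts[6:], dtype=object))
    alleles = np.array(rows, dtype=object).reshape(len(rows), m, 2)
    dosages = np.full((len(rows), m), np.nan)
    for j in range(m):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        if observed.size == 0:
            continue
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise ValueError(f"SNP {mp.snp_id[j]!r} has more than two alleles")
        if len(uniq) == 1:
            counted_mask = np.zeros(col.shape, dtype=bool)  # monomorphic: dosage 0
        else:
            # count the minor allele; ties -> lexicographically larger
            if counts[0] == counts[1]:
                counted = max(uniq)
            else:
                counted = uniq[np.argmin(counts)]
            counted_mask = col == counted
        missing = (col == "0").any(axis=1)
        dosages[:, j] = counted_mask.sum(axis=1).astype(float)
        dosages[missing, j] = np.nan
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=list(mp.snp_id),
        chromosomes=mp.chrom.to_numpy(),
        positions=mp.pos.to_numpy(),
        dosages=dosages,
    )


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.dosages, index=geno.sample_ids, columns=geno.snp_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep=_MISSING_DOSAGE)
    meta = pd.DataFrame(
        {"snp_id": geno.snp_ids, "chrom": geno.chromosomes, "pos": geno.positions}
    )
    meta.to_csv(Path(path).with_suffix(".snps.tsv"), sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=[_MISSING_DOSAGE])
    meta_path = Path(path).with_suffix(".snps.tsv")
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype={"chrom": str})
        chroms = meta.chrom.to_numpy()
        pos = meta.pos.to_numpy()
    else:
        chroms = np.array(["0"] * df.shape[1])
        pos = np.arange(1, df.shape[1] + 1, dtype=np.int64)
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        snp_ids=list(df.columns),
        chromosomes=chroms,
        positions=pos,
        dosages=df.to_numpy(dtype=float),
    )


def write_annotation_tsv(annot: RegionAnnotation, path: str | Path) -> None:
    df = annot.classes.rename("region").rename_axis("snp_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> RegionAnnotation:
    df = pd.read_csv(path, sep="\t")
    return RegionAnnotation(pd.Series(df.region.values, index=df.snp_id, dtype=object))


def write_phenotypes_tsv(
    sample_ids: list[str], y: np.ndarray, path: str | Path, trait: str = "trait"
) -> None:
    pd.DataFrame({"sample_id": sample_ids, trait: y}).to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    trait_col = df.columns[1]
    return [str(s) for s in df.sample_id], df[trait_col].to_numpy(dtype=float)


def write_true_components(truth: TrueComponents, path: str | Path) -> None:
    payload = {
        "mu": truth.mu,
        "g": {k: v.tolist() for k, v in truth.g.items()},
        "d": truth.d.tolist(),
        "e": truth.e.tolist(),
        "variance_fractions": truth.variance_fractions,
    }
    Path(path).write_text(json.dumps(payload))


def read_true_components(path: str | Path) -> TrueComponents:
    payload = json.loads(Path(path).read_text())
    return TrueComponents(
        mu=payload["mu"],
        g={k: np.asarray(v) for k, v in payload["g"].items()},
        d=np.asarray(payload["d"]),
        e=np.asarray(payload["e"]),
        variance_fractions=payload["variance_fractions"],
    )


def write_kernel_tsv(K: KernelMatrix, path: str | Path) -> None:
    df = pd.DataFrame(K.values, index=K.sample_ids, columns=K.sample_ids)
    df.index.name = f"{K.kind}:{K.region}:{K.n_snps_used}"
    df.to_csv(path, sep="\t")


def read_kernel_tsv(path: str | Path) -> KernelMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    kind, region, n_used = str(df.index.name).split(":")
    return KernelMatrix(
        sample_ids=[str(s) for s in df.index],
        values=df.to_numpy(dtype=float),
        kind=kind,
        region=region,
        n_snps_used=int(n_used),
    )
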