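"""Readers and writers for the standard interchange formats.

PLINK text (.ped/.map) and a minimal VCF 4.2 (GT only) carry genotypes;
BED6 and GFF3 carry gene annotation; phenotypes and covariates travel as
headered TSV. Gene coordinates are normalized internally to 1-based
inclusive; BED's 0-based half-open intervals are converted on read and
write.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, ConfigurationError, GeneModel, GenotypeMatrix

__all__ = [
    "write_ped_map",
    "read_ped_map",
    "write_vcf",
    "read_vcf",
    "write_bed",
    "read_bed",
    "write_gff3",
    "read_gff3",
    "write_phenotypes",
    "read_phenotypes",
]


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def write_ped_map(g: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write white-space-delimited .ped/.map files.

    Genotype code counts the first allele of each SNP's pair; missing
    calls become ``0 0``.
    """
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    pd.DataFrame(
        {
            "chrom": g.chrom,
            "snp_id": g.snp_ids,
            "cm": np.zeros(g.n_snps, dtype=int),
            "pos": g.pos_bp,
        }
    ).to_csv(map_path, sep=" ", header=False, index=False)

    a = np.array([al[0] for al in g.alleles], dtype=object)
    b = np.array([al[1] for al in g.alleles], dtype=object)
    with open(ped_path, "w") as fh:
        for i in range(g.n_individuals):
            row = g.codes[i]
            first = np.where(row >= 1, a, b)
            second = np.where(row == 2, a, b)
            first = np.where(row == MISSING, "0", first)
            second = np.where(row == MISSING, "0", second)
            alleles = " ".join(f"{x} {y}" for x, y in zip(first, second))
            fh.write(f"FAM {g.individual_ids[i]} 0 0 0 -9 {alleles}\n")
    return ped_path, map_path


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    """Read PLINK text genotypes.

    The counted allele of each SNP is the minor allele observed in the
    file (ties broken toward the allele seen first), the usual PLINK
    orientation.
    """
    prefix = Path(prefix)
    map_df = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str, "snp_id": str},
    )
    m = len(map_df)
    ids, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ConfigurationError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}"
                )
            ids.append(parts[1])
            rows.append(parts[6:])
    allele_arr = np.array(rows, dtype=object).reshape(len(rows), m, 2)

    codes = np.full((len(rows), m), MISSING, dtype=np.int8)
    alleles = np.empty((m, 2), dtype=object)
    for j in range(m):
        col = allele_arr[:, j, :]
        observed = col[col != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) == 0:
            alleles[j] = ("A", "B")
            continue
        if len(uniq) > 2:
            raise ConfigurationError(f"SNP {map_df.snp_id[j]} has >2 alleles: {uniq}")
        order = np.argsort(counts, kind="stable")  # minor first
        minor = uniq[order[0]]
        major = uniq[order[-1]] if len(uniq) > 1 else "0"
        alleles[j] = (minor, major if major != "0" else minor)
        present = (col != "0").all(axis=1)
        codes[present, j] = (col[present] == minor).sum(axis=1)
    return GenotypeMatrix(
        codes=codes,
        snp_ids=map_df.snp_id.to_numpy(dtype=object),
        chrom=map_df.chrom.to_numpy(dtype=object),
        pos_bp=map_df.pos.to_numpy(dtype=np.int64),
        alleles=alleles,
        individual_ids=np.array(ids, dtype=object),
    )


# ---------------------------------------------------------------------------
# minimal VCF 4.2
# ---------------------------------------------------------------------------

def write_vcf(g: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal VCF 4.2 with a GT field only.

    REF is the second (major) allele, ALT the counted allele, so the
    ALT-dosage of each genotype equals the stored code.
    """
    path = Path(path)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.individual_ids))
            + "\n"
        )
        for j in range(g.n_snps):
            minor, major = g.alleles[j]
            gts = "\t".join(gt_map[int(c)] for c in g.codes[:, j])
            fh.write(
                f"{g.chrom[j]}\t{g.pos_bp[j]}\t{g.snp_ids[j]}\t{major}\t{minor}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read genotypes (GT only) from a VCF via cyvcf2; codes count ALT."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires the optional cyvcf2 dependency") from exc

    vcf = VCF(str(path))
    individual_ids = np.array(vcf.samples, dtype=object)
    codes_cols, snp_ids, chroms, pos, alleles = [], [], [], [], []
    for var in vcf:
        col = np.full(len(individual_ids), MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a = [x for x in gt[:-1] if x >= 0]
            if len(a) == 2:
                col[i] = sum(1 for x in a if x > 0)
        codes_cols.append(col)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        pos.append(var.POS)
        alt = var.ALT[0] if var.ALT else "."
        alleles.append((alt, var.REF))
    vcf.close()
    return GenotypeMatrix(
        codes=np.array(codes_cols, dtype=np.int8).T,
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        alleles=np.array(alleles, dtype=object),
        individual_ids=individual_ids,
    )


# ---------------------------------------------------------------------------
# gene annotation: BED6 and GFF3
# ---------------------------------------------------------------------------

def write_bed(genes: Sequence[GeneModel], path: str | Path) -> Path:
    """Write genes as BED6 (0-based half-open)."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start_bp - 1}\t{g.end_bp}\t{g.gene_id}\t0\t+\n"
            )
    return path


def read_bed(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(4),
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "name": str},
    )
    return [
        GeneModel(
            gene_id=str(name),
            chrom=str(chrom),
            start_bp=int(start) + 1,
            end_bp=int(end),
        )
        for chrom, start, end, name in df.itertuples(index=False)
    ]


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> Path:
    """Write genes as GFF3 gene features (1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.symbol or g.gene_id};biotype={g.biotype}"
            fh.write(
                f"{g.chrom}\tgenegwas\tgene\t{g.start_bp}\t{g.end_bp}\t.\t+\t.\t{attrs}\n"
            )
    return path


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GFF3 file (non-gene features ignored)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            genes.append(
                GeneModel(
                    gene_id=attrs.get("ID", f"{parts[0]}:{parts[3]}-{parts[4]}"),
                    symbol=attrs.get("Name", ""),
                    biotype=attrs.get("biotype", "protein_coding"),
                    chrom=parts[0],
                    start_bp=int(parts[3]),
                    end_bp=int(parts[4]),
                )
            )
    return genes


# ---------------------------------------------------------------------------
# phenotype / covariate tables
# ---------------------------------------------------------------------------

def write_phenotypes(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if "individual_id" not in df.columns:
        raise ConfigurationError(
            f"{path}: phenotype/covariate table needs an 'individual_id' column"
        )
    return df
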