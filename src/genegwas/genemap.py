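"""SNP-to-gene assignment by physical distance.

A SNP belongs to a gene when it falls within a flanking window around
the annotated gene span (default +/-20 kb, boundaries inclusive), and a
gene enters the gene-based test only when at least ``min_snps`` markers
map to it (default 5). A SNP may belong to several overlapping genes.
Nearest-gene annotation reports the distance to the closest gene edge,
or "in" for SNPs inside a gene body.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import (
    ChromosomeMismatchError,
    GeneModel,
    GenotypeMatrix,
    logger,
)

__all__ = ["GeneSnpAssignment", "assign_snps_to_genes", "nearest_gene"]

IN_GENE = "in"  # sentinel distance for SNPs inside the gene body


@dataclass
class GeneSnpAssignment:
    """Mapping gene_id -> ordered SNP indices, plus bookkeeping."""

    snp_indices: dict[str, np.ndarray]
    genes: dict[str, GeneModel]
    window_bp: int
    min_snps: int
    n_genes_in: int = 0
    n_genes_dropped: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.snp_indices)

    def snp_count(self, gene_id: str) -> int:
        return len(self.snp_indices[gene_id])

    def ordered_gene_ids(self) -> list[str]:
        """Gene ids sorted by chromosome then start position."""
        return sorted(
            self.snp_indices,
            key=lambda gid: (self.genes[gid].chrom, self.genes[gid].start_bp),
        )


def assign_snps_to_genes(
    g: GenotypeMatrix,
    genes: Sequence[GeneModel],
    window_bp: int = 20_000,
    min_snps: int = 5,
) -> GeneSnpAssignment:
    """Assign SNPs to genes by the closed +/-window rule.

    A SNP at exactly ``start - window_bp`` or ``end + window_bp`` is
    included. Genes with fewer than ``min_snps`` mapped SNPs are dropped
    and counted. Raises :class:`ChromosomeMismatchError` when the
    annotation uses chromosome labels absent from the genotype map.
    """
    map_chroms = set(g.chrom.tolist())
    bad = sorted({gene.chrom for gene in genes} - map_chroms)
    if bad:
        raise ChromosomeMismatchError(
            f"annotation chromosomes {bad} not present in genotype map "
            f"(map has {sorted(map_chroms)})"
        )

    # per-chromosome sorted position index for binary search
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in map_chroms:
        idx = np.nonzero(g.chrom == c)[0]
        order = np.argsort(g.pos_bp[idx], kind="stable")
        idx = idx[order]
        by_chrom[c] = (g.pos_bp[idx], idx)

    assignment: dict[str, np.ndarray] = {}
    gene_index: dict[str, GeneModel] = {}
    dropped = 0
    for gene in genes:
        pos, idx = by_chrom[gene.chrom]
        lo, hi = gene.window(window_bp)
        a = np.searchsorted(pos, lo, side="left")
        b = np.searchsorted(pos, hi, side="right")
        hits = idx[a:b]
        if len(hits) < min_snps:
            dropped += 1
            continue
        assignment[gene.gene_id] = hits
        gene_index[gene.gene_id] = gene

    logger.info(
        "genemap: %d/%d genes retained (>= %d SNPs in +/-%d bp window)",
        len(assignment),
        len(genes),
        min_snps,
        window_bp,
    )
    return GeneSnpAssignment(
        snp_indices=assignment,
        genes=gene_index,
        window_bp=window_bp,
        min_snps=min_snps,
        n_genes_in=len(genes),
        n_genes_dropped=dropped,
    )


def nearest_gene(
    chrom: str, pos_bp: int, genes: Sequence[GeneModel]
) -> tuple[GeneModel | None, int | str | None]:
    """Nearest gene to a map position on the same chromosome.

    Returns ``(gene, "in")`` when the position lies inside the gene body
    (distance zero), ``(gene, distance_bp)`` otherwise, and
    ``(None, None)`` when the chromosome carries no annotated gene.
    Ties go to the first gene in (chrom, start) order.
    """
    candidates = sorted(
        (g for g in genes if g.chrom == chrom), key=lambda g: (g.start_bp, g.end_bp)
    )
    if not candidates:
        return None, None
    best: GeneModel | None = None
    best_dist: int | None = None
    for gene in candidates:
        if gene.start_bp <= pos_bp <= gene.end_bp:
            return gene, IN_GENE
        dist = min(abs(pos_bp - gene.start_bp), abs(pos_bp - gene.end_bp))
        if best_dist is None or dist < best_dist:
            best, best_dist = gene, dist
    return best, best_dist
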