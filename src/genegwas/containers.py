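"""Core in-memory containers shared across the pipeline.

Genotypes are held as additive minor-allele dosages (0/1/2) in a dense
``int8`` matrix with ``-1`` marking a missing call — the compact encoding
used by most chip-GWAS tooling. Gene annotations are 1-based inclusive
intervals, the convention of GFF3 and of published gene tables; BED input
is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger("genegwas")

#: sentinel for a missing genotype call in ``GenotypeMatrix.codes``
MISSING: int = -1


class ConfigurationError(ValueError):
    """A simulation or analysis parameter is outside its valid domain."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal
    (e.g. all SNPs monomorphic, all individuals removed)."""


class ChromosomeMismatchError(ValueError):
    """Chromosome labels of an annotation do not match the genotype map."""


class RankError(ValueError):
    """A requested decomposition exceeds the rank of the data."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive genotype codes plus per-SNP map metadata.

    Parameters
    ----------
    codes
        ``(n_individuals, n_snps)`` int8 array with values in
        ``{0, 1, 2, MISSING}`` counting copies of allele ``A`` (the allele
        stored first in ``alleles``).
    snp_ids, chrom, pos_bp, alleles
        Per-SNP identifier, chromosome label, 1-based position, and the
        ``(A, B)`` allele pair (``A`` is the counted allele).
    individual_ids
        Per-row sample identifier.
    """

    codes: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    alleles: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n, m = self.codes.shape
        for name, arr, expect in (
            ("snp_ids", self.snp_ids, m),
            ("chrom", self.chrom, m),
            ("pos_bp", self.pos_bp, m),
            ("individual_ids", self.individual_ids, n),
        ):
            if arr.shape[0] != expect:
                raise ConfigurationError(
                    f"GenotypeMatrix.{name} has length {arr.shape[0]}, expected {expect}"
                )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ConfigurationError(
                f"GenotypeMatrix.codes contains {bad.sum()} values outside {{0,1,2,missing}}"
            )

    # -- basic shape --------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, m)`` mask of missing calls."""
        return self.codes == MISSING

    # -- derived numeric views ----------------------------------------
    def dosages(self, impute: bool = True) -> np.ndarray:
        """Float copy of the codes; missing entries as NaN or per-SNP mean.

        Mean imputation of missing calls is the standard chip-GWAS
        convention before centering for kinship or PCA.
        """
        x = self.codes.astype(np.float64)
        miss = self.codes == MISSING
        if not miss.any():
            return x
        x[miss] = np.nan
        if impute:
            col_mean = np.nanmean(x, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.nonzero(miss)
            x[idx] = col_mean[idx[1]]
        return x

    def allele_frequency(self) -> np.ndarray:
        """Frequency of the counted (``A``) allele among non-missing calls.

        All-missing SNPs get NaN.
        """
        x = self.codes.astype(np.float64)
        x[self.codes == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(x, axis=0) / 2.0

    # -- subsetting ----------------------------------------------------
    def subset(
        self,
        individuals: Sequence[int] | np.ndarray | None = None,
        snps: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given row/column indices
        (integer positions or boolean masks)."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if ind.dtype == bool:
            ind = np.nonzero(ind)[0]
        if snp.dtype == bool:
            snp = np.nonzero(snp)[0]
        return GenotypeMatrix(
            codes=self.codes[np.ix_(ind, snp)],
            snp_ids=self.snp_ids[snp],
            chrom=self.chrom[snp],
            pos_bp=self.pos_bp[snp],
            alleles=self.alleles[snp],
            individual_ids=self.individual_ids[ind],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            codes=self.codes.copy(),
            snp_ids=self.snp_ids.copy(),
            chrom=self.chrom.copy(),
            pos_bp=self.pos_bp.copy(),
            alleles=self.alleles.copy(),
            individual_ids=self.individual_ids.copy(),
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: 1-based inclusive genomic interval plus identifiers."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    symbol: str = ""
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ConfigurationError(
                f"gene {self.gene_id}: start_bp {self.start_bp} > end_bp {self.end_bp}"
            )
        if self.start_bp < 1:
            raise ConfigurationError(f"gene {self.gene_id}: start_bp must be >= 1 (1-based)")

    @property
    def midpoint(self) -> float:
        return (self.start_bp + self.end_bp) / 2.0

    def window(self, window_bp: int) -> tuple[int, int]:
        """Closed interval extended by ``window_bp`` on both sides."""
        return max(1, self.start_bp - window_bp), self.end_bp + window_bp
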