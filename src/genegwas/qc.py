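"""Marker- and individual-level genotype quality control.

Standard chip-QC filters: individual missingness, SNP call rate, minor
allele frequency, minimum genotype-class count, a Hardy-Weinberg exact
test, and removal of SNPs with missing map positions. Individuals are
filtered first, then SNP statistics are computed on the retained
individuals and each removed SNP is attributed to the first filter that
caught it (unmapped -> call rate -> MAF -> genotype count -> HWE).

The minimum genotype-count rule is applied to the least frequent of the
three genotype classes {0, 1, 2} present in the data; a class with zero
carriers does not count against the SNP (monomorphic SNPs are instead
caught by the MAF filter). This reading of "genotype occurring in fewer
than N individuals" is recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .containers import MISSING, DegenerateInputError, GenotypeMatrix, logger

__all__ = [
    "QcThresholds",
    "QcReport",
    "snp_call_rate",
    "individual_call_rate",
    "minor_allele_frequency",
    "genotype_counts",
    "hwe_exact_test",
    "hwe_test",
    "apply_qc",
    "mendel_error_filter",
]


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; defaults are the usual chip-GWAS choices."""

    min_call_rate: float = 0.90
    min_maf: float = 0.05
    min_genotype_count: int = 5
    min_hwe_p: float = 1e-6
    max_individual_missing: float = 0.10
    drop_unmapped: bool = True


@dataclass
class QcReport:
    """Bookkeeping of what was removed and why."""

    thresholds: QcThresholds
    n_individuals_in: int = 0
    n_individuals_out: int = 0
    n_snps_in: int = 0
    n_snps_out: int = 0
    removed_individuals_missingness: int = 0
    removed_snps: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        return d


# ---------------------------------------------------------------------------
# per-SNP / per-individual statistics
# ---------------------------------------------------------------------------

def snp_call_rate(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing genotypes per SNP, in [0, 1]."""
    if g.n_snps == 0 or g.n_individuals == 0:
        raise DegenerateInputError("empty genotype matrix")
    return 1.0 - (g.codes == MISSING).mean(axis=0)


def individual_call_rate(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing genotypes per individual."""
    if g.n_snps == 0 or g.n_individuals == 0:
        raise DegenerateInputError("empty genotype matrix")
    return 1.0 - (g.codes == MISSING).mean(axis=1)


def minor_allele_frequency(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency over non-missing genotypes.

    The counted-allele frequency is folded so the result is always the
    minor one (<= 0.5). All-missing SNPs yield NaN and are left for
    :func:`apply_qc` to drop via the call-rate filter.
    """
    p = g.allele_frequency()
    with np.errstate(invalid="ignore"):
        return np.minimum(p, 1.0 - p)


def genotype_counts(g: GenotypeMatrix) -> np.ndarray:
    """``(n_snps, 3)`` counts of genotype classes 0/1/2, ignoring missing."""
    return np.stack([(g.codes == k).sum(axis=0) for k in (0, 1, 2)], axis=1)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact two-sided HWE test p-value from genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more likely than the observed one (the
    standard exact formulation for biallelic markers). Monomorphic SNPs
    return 1 by convention.
    """
    n_het = int(n_het)
    n = int(n_hom_minor) + n_het + int(n_hom_major)
    n_minor = 2 * int(n_hom_minor) + n_het
    if n == 0 or n_minor == 0 or n_minor == 2 * n:
        return 1.0
    # fold so n_minor really is the rarer allele
    if n_minor > n:
        n_minor = 2 * n - n_minor

    # Unnormalized probabilities over all feasible heterozygote counts
    # (same parity as the minor-allele count), built by the ratio
    # recurrence anchored at the modal count so neither tail overflows.
    h_min = n_minor % 2
    h_max = n_minor
    h_mode = int(round(n_minor * (2 * n - n_minor) / (2.0 * n)))
    if h_mode % 2 != h_min:
        h_mode += 1
    h_mode = min(max(h_mode, h_min), h_max)
    probs = {h_mode: 1.0}
    h = h_mode
    while h - 2 >= h_min:
        hom_r = (n_minor - h) // 2
        hom_c = n - h - hom_r
        # P(h-2) = P(h) * h*(h-1) / (4*(hom_r+1)*(hom_c+1))
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = h_mode
    while h + 2 <= h_max:
        hom_r = (n_minor - h) // 2
        hom_c = n - h - hom_r
        if hom_r == 0 or hom_c == 0:
            break
        # P(h+2) = P(h) * 4*hom_r*hom_c / ((h+1)*(h+2))
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 1.0) * (h + 2.0))
        h += 2
    total = sum(probs.values())
    if n_het not in probs:  # inconsistent counts (should not happen post-fold)
        return 1.0
    p_obs = probs[n_het]
    tail = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
    return float(min(1.0, tail / total))


def hwe_test(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP exact HWE p-values in (0, 1]."""
    counts = genotype_counts(g)
    maf_is_alt = np.nan_to_num(g.allele_frequency(), nan=0.0) > 0.5
    out = np.empty(g.n_snps)
    for j in range(g.n_snps):
        c0, c1, c2 = counts[j]
        if maf_is_alt[j]:
            c0, c2 = c2, c0
        out[j] = hwe_exact_test(c2, c1, c0)
    return out


# ---------------------------------------------------------------------------
# the combined filter
# ---------------------------------------------------------------------------

_SNP_FILTER_ORDER = ("unmapped", "call_rate", "maf", "genotype_count", "hwe")


def apply_qc(
    g: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply all filters; returns the surviving matrix and a report.

    Individuals with too many missing genotypes are removed first; SNP
    statistics are then computed on the retained individuals.
    """
    thr = thresholds or QcThresholds()
    report = QcReport(
        thresholds=thr,
        n_individuals_in=g.n_individuals,
        n_snps_in=g.n_snps,
    )
    report.notes.append(
        "genotype-count filter applied to the least frequent observed genotype class"
    )

    ind_cr = individual_call_rate(g)
    keep_ind = ind_cr >= 1.0 - thr.max_individual_missing
    report.removed_individuals_missingness = int((~keep_ind).sum())
    if not keep_ind.any():
        raise DegenerateInputError("all individuals removed by missingness filter")
    g = g.subset(individuals=keep_ind)

    removal = np.full(g.n_snps, "", dtype=object)

    def _mark(mask: np.ndarray, name: str) -> None:
        fresh = mask & (removal == "")
        removal[fresh] = name

    if thr.drop_unmapped:
        _mark((g.pos_bp <= 0) | (g.chrom == "") | (g.chrom == "0"), "unmapped")
    _mark(snp_call_rate(g) < thr.min_call_rate, "call_rate")
    with np.errstate(invalid="ignore"):
        maf = minor_allele_frequency(g)
    _mark(np.isnan(maf) | (maf < thr.min_maf), "maf")

    counts = genotype_counts(g)
    present = counts > 0
    min_class = np.where(present, counts, np.iinfo(np.int64).max).min(axis=1)
    polymorphic = present.sum(axis=1) > 1
    _mark(polymorphic & (min_class < thr.min_genotype_count), "genotype_count")

    _mark(hwe_test(g) < thr.min_hwe_p, "hwe")

    keep_snp = removal == ""
    for name in _SNP_FILTER_ORDER:
        report.removed_snps[name] = int((removal == name).sum())
    if not keep_snp.any():
        raise DegenerateInputError("all SNPs removed by QC filters")

    out = g.subset(snps=keep_snp)
    report.n_individuals_out = out.n_individuals
    report.n_snps_out = out.n_snps
    logger.info(
        "QC: %d/%d individuals, %d/%d SNPs retained",
        report.n_individuals_out,
        report.n_individuals_in,
        report.n_snps_out,
        report.n_snps_in,
    )
    return out, report


def mendel_error_filter(
    g: GenotypeMatrix, pedigree: Any = None, max_error_rate: float = 0.02
) -> GenotypeMatrix:
    """Hook for a pedigree-based Mendelian-error filter.

    Pedigree records are outside this package's data model; without them
    the filter is a no-op and says so.
    """
    if pedigree is None:
        logger.info("mendel_error_filter: no pedigree supplied, no-op")
        return g
    raise NotImplementedError("pedigree-based Mendel filtering is not implemented")
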