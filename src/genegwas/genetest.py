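"""Two-stage gene-based association test.

Stage 1 orthogonalizes the SNPs of a gene: the variance-covariance
matrix of the (mean-imputed, centered) genotype codes is
eigendecomposed and the smallest number K of leading components whose
eigenvalues cover at least 85% of the total variance is retained; the
PC scores are the centered genotype matrix times those eigenvectors.

Stage 2 tests each PC against the adjusted trait by its Pearson
correlation r, converted to a two-sided p-value via
``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` on n-2 degrees of freedom, and
combines the K per-PC p-values with Fisher's statistic
``chi2 = -2 * sum_k ln p_k``, which under the null follows a chi-square
distribution with 2K degrees of freedom because the PCs are mutually
orthogonal. Genome-wide significance uses Bonferroni correction over
the number of genes actually tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .containers import DegenerateInputError, GenotypeMatrix, logger
from .adjust import AdjustedPhenotype
from .genemap import GeneSnpAssignment

__all__ = [
    "GenePcDecomposition",
    "GeneTestResult",
    "gene_pca",
    "pc_pvalues",
    "fisher_combination",
    "bonferroni_threshold",
    "genome_scan",
    "precompute_gene_pcs",
    "scan_decompositions",
]

#: smallest positive p-value admitted into the log; keeps chi2 finite
#: with no effect on ranking
P_FLOOR = 1e-300


@dataclass
class GenePcDecomposition:
    """Within-gene PCA: retained scores and variance bookkeeping."""

    gene_id: str
    pc_scores: np.ndarray  # (n_individuals, K)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    variance_fraction_captured: float
    k: int
    n_snps: int
    n_dropped_zero_variance: int = 0


@dataclass
class GeneTestResult:
    """Fisher-combined gene-level association result."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    symbol: str
    k: int
    pc_pvalues: np.ndarray
    chi2_stat: float
    df: int
    gene_p: float
    significant: bool = False


# ---------------------------------------------------------------------------
# Stage 1: within-gene PCA
# ---------------------------------------------------------------------------

def gene_pca(
    g: GenotypeMatrix,
    snp_indices: np.ndarray,
    variance_target: float = 0.85,
    gene_id: str = "",
) -> GenePcDecomposition:
    """Eigendecompose a gene's SNP covariance and keep the top PCs.

    ``K`` is the smallest count whose cumulative eigenvalue fraction
    reaches ``variance_target``. Zero-variance SNP columns are dropped
    (logged); a gene whose SNPs are all zero-variance is degenerate.
    """
    if not (0.0 < variance_target <= 1.0):
        raise DegenerateInputError(f"variance_target must be in (0, 1], got {variance_target}")
    x = g.subset(snps=np.asarray(snp_indices)).dosages(impute=True)
    variances = x.var(axis=0)
    keep = variances > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("gene %s: dropped %d zero-variance SNP columns", gene_id, n_dropped)
    if not keep.any():
        raise DegenerateInputError(f"gene {gene_id}: all SNP columns have zero variance")
    x = x[:, keep]
    xc = x - x.mean(axis=0)
    n = x.shape[0]
    cov = (xc.T @ xc) / (n - 1)

    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    total = eigvals.sum()
    if total <= 0:
        raise DegenerateInputError(f"gene {gene_id}: zero total variance")
    cumfrac = np.cumsum(eigvals) / total
    k = int(np.searchsorted(cumfrac, variance_target - 1e-12) + 1)
    k = min(k, len(eigvals))

    # deterministic sign: largest-|loading| entry positive
    vecs = eigvecs[:, :k].copy()
    for j in range(k):
        lead = np.argmax(np.abs(vecs[:, j]))
        if vecs[lead, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = xc @ vecs
    return GenePcDecomposition(
        gene_id=gene_id,
        pc_scores=scores,
        eigenvalues=eigvals,
        variance_fraction_captured=float(cumfrac[k - 1]),
        k=k,
        n_snps=x.shape[1],
        n_dropped_zero_variance=n_dropped,
    )


# ---------------------------------------------------------------------------
# Stage 2: per-PC correlation tests and Fisher's combination
# ---------------------------------------------------------------------------

def pc_pvalues(pcs: GenePcDecomposition, y: np.ndarray | AdjustedPhenotype, trait: str | None = None) -> np.ndarray:
    """Two-sided p-value of the trait-PC Pearson correlation, per PC.

    Zero-variance PC score columns (possible after aggressive rounding)
    are excluded with a warning, reducing K.
    """
    if isinstance(y, AdjustedPhenotype):
        if trait is None:
            trait = y.residuals.columns[0]
        y = y.trait(trait)
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    scores = pcs.pc_scores
    if scores.shape[0] != n:
        raise DegenerateInputError(
            f"gene {pcs.gene_id}: {scores.shape[0]} score rows vs {n} phenotypes"
        )
    if n <= pcs.k + 2:
        raise DegenerateInputError(
            f"gene {pcs.gene_id}: n={n} too small for K={pcs.k} PCs"
        )
    sd = scores.std(axis=0)
    usable = sd > 0
    if not usable.all():
        warnings.warn(
            f"gene {pcs.gene_id}: {(~usable).sum()} zero-variance PC columns excluded",
            stacklevel=2,
        )
    s = scores[:, usable]
    yc = y - y.mean()
    y_sd = yc.std()
    if y_sd == 0:
        raise DegenerateInputError("phenotype has zero variance")
    r = (s - s.mean(axis=0)).T @ yc / (n * s.std(axis=0) * y_sd)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(p)] = 0.0  # |r| == 1 exactly
    return np.minimum(p, 1.0)


def fisher_combination(p_values: np.ndarray) -> tuple[float, int, float]:
    """Fisher's combination of K independent p-values.

    Returns ``(chi2_stat, df, gene_p)`` with ``chi2 = -2 sum ln p_k`` and
    ``gene_p`` the upper-tail chi-square probability on ``2K`` degrees of
    freedom. Zeros are clamped to ``P_FLOOR`` with a warning; values
    outside [0, 1] are a domain error.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1 or p.size < 1:
        raise DegenerateInputError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DegenerateInputError(f"p-values outside [0, 1]: {p}")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to 1e-300 before logging", stacklevel=2)
        p = np.maximum(p, P_FLOOR)
    k = p.size
    chi2 = float(-2.0 * np.sum(np.log(p)))
    gene_p = float(scipy.stats.chi2.sf(chi2, df=2 * k))
    return chi2, 2 * k, max(gene_p, 0.0)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise DegenerateInputError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def precompute_gene_pcs(
    g: GenotypeMatrix,
    assignment: GeneSnpAssignment,
    variance_target: float = 0.85,
) -> dict[str, GenePcDecomposition]:
    """Stage-1 decompositions for every retained gene.

    Phenotype-independent, so callers testing many traits (or many
    permutations) against the same genotypes compute this once.
    Degenerate genes (all SNPs zero variance) are skipped with a log entry.
    """
    out: dict[str, GenePcDecomposition] = {}
    for gene_id in assignment.ordered_gene_ids():
        try:
            out[gene_id] = gene_pca(
                g, assignment.snp_indices[gene_id], variance_target, gene_id=gene_id
            )
        except DegenerateInputError as exc:
            logger.warning("skipping gene %s: %s", gene_id, exc)
    return out


def scan_decompositions(
    decompositions: dict[str, GenePcDecomposition],
    assignment: GeneSnpAssignment,
    y: np.ndarray,
    alpha: float = 0.05,
) -> list[GeneTestResult]:
    """Stage-2 scan of precomputed gene decompositions against a trait."""
    if not decompositions:
        raise DegenerateInputError("no genes to test")
    n_tested = len(decompositions)
    threshold = bonferroni_threshold(n_tested, alpha)
    results = []
    for gene_id, dec in decompositions.items():
        gene = assignment.genes[gene_id]
        p_k = pc_pvalues(dec, y)
        chi2, df, gene_p = fisher_combination(p_k)
        results.append(
            GeneTestResult(
                gene_id=gene_id,
                chrom=gene.chrom,
                start_bp=gene.start_bp,
                end_bp=gene.end_bp,
                symbol=gene.symbol,
                k=len(p_k),
                pc_pvalues=p_k,
                chi2_stat=chi2,
                df=df,
                gene_p=gene_p,
                significant=gene_p < threshold,
            )
        )
    results.sort(key=lambda r: (r.chrom, r.start_bp))
    return results


def genome_scan(
    g: GenotypeMatrix,
    assignment: GeneSnpAssignment,
    y: np.ndarray | AdjustedPhenotype,
    trait: str | None = None,
    variance_target: float = 0.85,
    alpha: float = 0.05,
) -> list[GeneTestResult]:
    """Full two-stage scan: gene PCA then Fisher combination per gene.

    Significance is Bonferroni-corrected over the genes actually tested.
    """
    if assignment.n_genes == 0:
        raise DegenerateInputError("empty gene-SNP assignment")
    if isinstance(y, AdjustedPhenotype):
        if trait is None:
            trait = y.residuals.columns[0]
        y = y.trait(trait)
    decs = precompute_gene_pcs(g, assignment, variance_target)
    return scan_decompositions(decs, assignment, np.asarray(y, dtype=np.float64), alpha)
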