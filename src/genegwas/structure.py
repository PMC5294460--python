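"""Population structure: VanRaden genomic relationships and structure PCs.

The genomic relationship matrix follows VanRaden's first estimator,
``G = Z Z' / (2 * sum_j p_j (1 - p_j))`` with ``Z`` the genotype matrix
centered at twice the allele frequency. Structure principal components
are computed from a random fraction of SNPs (defaults: 10% of markers,
five components), the usual device for correcting stratification while
keeping the eigendecomposition cheap and dampening local-LD artifacts.
Missing genotypes are mean-imputed per SNP before centering in both
computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DegenerateInputError, GenotypeMatrix, RankError

__all__ = ["KinshipMatrix", "StructurePCs", "vanraden_grm", "structure_pcs"]


@dataclass
class KinshipMatrix:
    """Symmetric n x n additive relationship coefficients."""

    values: np.ndarray
    individual_ids: np.ndarray
    method: str = "vanraden"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise DegenerateInputError("kinship matrix must be square")
        if len(self.individual_ids) != self.values.shape[0]:
            raise DegenerateInputError("kinship ids do not match matrix dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class StructurePCs:
    """Individual-level principal component scores for structure correction."""

    scores: np.ndarray  # (n, k)
    explained_variance_fraction: np.ndarray  # (k,), non-increasing
    individual_ids: np.ndarray
    snp_fraction: float
    seed: int
    snp_indices: np.ndarray  # which SNPs were sampled
    centering: str = "observed-mean"

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def vanraden_grm(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix.

    Allele frequencies are taken from the data; missing calls are
    mean-imputed per SNP (equivalently, contribute zero after centering).
    Monomorphic SNPs contribute nothing to numerator or denominator; if
    every SNP is monomorphic the denominator vanishes and the input is
    rejected as degenerate.
    """
    x = g.dosages(impute=True)
    p = x.mean(axis=0) / 2.0
    z = x - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise DegenerateInputError(
            "VanRaden denominator is zero: all SNPs are monomorphic"
        )
    values = (z @ z.T) / denom
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return KinshipMatrix(values=values, individual_ids=g.individual_ids.copy())


def structure_pcs(
    g: GenotypeMatrix,
    snp_fraction: float = 0.10,
    k: int = 5,
    seed: int = 0,
) -> StructurePCs:
    """Top-k principal components from a random SNP subset.

    A fraction of SNP columns is sampled without replacement with the
    given seed, mean-imputed and centered by the observed column mean,
    and the scores of the top ``k`` components of the individual-level
    covariance are returned. Component signs follow the convention that
    the largest-magnitude SNP loading is positive.
    """
    if not (0.0 < snp_fraction <= 1.0):
        raise DegenerateInputError(f"snp_fraction must be in (0, 1], got {snp_fraction}")
    if k < 1 or k > g.n_individuals - 1:
        raise RankError(
            f"k={k} components requested for n={g.n_individuals} individuals"
        )
    rng = np.random.default_rng(seed)
    m = max(1, int(round(snp_fraction * g.n_snps)))
    snp_idx = np.sort(rng.choice(g.n_snps, size=m, replace=False))

    x = g.subset(snps=snp_idx).dosages(impute=True)
    xc = x - x.mean(axis=0)
    # economy SVD of the centered matrix: scores = U S, loadings = V
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if k > rank:
        raise RankError(f"k={k} exceeds the rank {rank} of the sampled genotype matrix")
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u[:, :k] * s[:k]
    var = s**2
    explained = var[:k] / var.sum()
    return StructurePCs(
        scores=scores,
        explained_variance_fraction=explained,
        individual_ids=g.individual_ids.copy(),
        snp_fraction=snp_fraction,
        seed=seed,
        snp_indices=snp_idx,
    )
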