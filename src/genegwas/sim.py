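"""Synthetic cattle-like GWAS data.

Generates a diploid population genotyped at dense biallelic SNPs with
haplotype-block LD, a gene map of multi-SNP genes, covariates (year, farm,
gender, fattening days, entering weight) and quantitative traits composed
of fixed effects, a kinship-driven polygenic term and a small number of
causal genes. Every downstream stage of the pipeline is testable against
the recorded ground truth with no external download.

LD model
--------
Haplotypes are simulated block-wise. Within a block all SNPs share one
allele frequency drawn from ``maf_range``; the allele at each SNP copies
the allele at the previous SNP with probability ``ld_decay`` and is drawn
fresh otherwise. This first-order copy process gives an adjacent-SNP
haplotype (and hence genotype) correlation of exactly ``ld_decay`` in
expectation, independent blocks, and genuinely correlated SNPs inside a
gene — the structure that makes within-gene PCA non-trivial.

Trait model
-----------
On a standardized scale, ``y* = fixed effects + c + g + e`` with
``g ~ N(0, sigma2_g * K)`` (``K`` the VanRaden kinship of the simulated
genotypes), ``c`` the summed causal-SNP effects scaled to explain
``h2_causal`` of the genetic-plus-residual variance, and
``e ~ N(0, 1 - h2_polygenic - h2_causal)``. The emitted trait is
``mean + sd * y*`` using carcass-trait-like location/scale per trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    ConfigurationError,
    GeneModel,
    GenotypeMatrix,
    logger,
)

__all__ = [
    "SimConfig",
    "SimOutput",
    "TraitTruth",
    "simulate_genotypes",
    "simulate_gene_map",
    "simulate_phenotypes",
    "simulate",
]

# rng stream indices so each stage can be regenerated independently
_STAGE_GENO, _STAGE_GENES, _STAGE_PHENO = 0, 1, 2

#: trait location/scale used to place the standardized trait on a
#: carcass-trait-like measurement scale (mean, sd)
TRAIT_SCALES: dict[str, tuple[float, float]] = {
    "BW": (40.0, 6.58),
    "pH": (5.63, 0.38),
}


@dataclass
class SimConfig:
    """Full parameterization of the synthetic population and traits.

    Defaults emulate a ~1,000-animal beef-cattle cohort genotyped on a
    dense SNP panel: ten thousand markers in 10-SNP LD blocks, several
    hundred multi-SNP genes, a bone-weight-like trait with polygenic
    heritability 0.41, and a handful of causal genes of modest effect.
    """

    n_individuals: int = 1000
    n_chromosomes: int = 5
    snps_per_chromosome: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_decay: float = 0.7
    snp_spacing_bp: int = 3000
    n_genes: int = 500
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    n_causal_genes: int = 3
    causal_snps_per_gene: int = 2
    h2_polygenic: float = 0.41
    h2_causal: float = 0.06
    fixed_effect_levels: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: {"year": (3, 0.3), "farm": (5, 0.3), "gender": (2, 0.3)}
    )
    continuous_effects: Mapping[str, float] = field(
        default_factory=lambda: {"fattening_days": 0.2, "entering_weight": 0.2}
    )
    trait_names: tuple[str, ...] = ("BW", "pH")
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_individuals",
            "n_chromosomes",
            "snps_per_chromosome",
            "ld_block_size",
            "snp_spacing_bp",
        ):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"SimConfig.{name} must be a positive count")
        for name in ("n_genes", "n_causal_genes", "causal_snps_per_gene"):
            if int(getattr(self, name)) < 0:
                raise ConfigurationError(f"SimConfig.{name} must be non-negative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("SimConfig.maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ConfigurationError("SimConfig.ld_decay must lie in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("SimConfig.missing_rate must lie in [0, 1)")
        for name in ("h2_polygenic", "h2_causal"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ConfigurationError(f"SimConfig.{name} must lie in [0, 1)")
        if self.h2_polygenic + self.h2_causal >= 1.0:
            raise ConfigurationError(
                "SimConfig.h2_polygenic + h2_causal must be < 1 "
                f"(got {self.h2_polygenic + self.h2_causal})"
            )
        glo, ghi = self.gene_length_range
        if not (0 < glo <= ghi):
            raise ConfigurationError("SimConfig.gene_length_range must be positive and ordered")

    def chromosome_length(self) -> int:
        return self.snps_per_chromosome * self.snp_spacing_bp

    def rng(self, stage: int) -> np.random.Generator:
        """Per-stage generator derived deterministically from the master seed."""
        return np.random.default_rng([int(self.seed), stage])

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown SimConfig fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("maf_range", "gene_length_range", "trait_names"):
            if key in d:
                d[key] = tuple(d[key])
        if "fixed_effect_levels" in d:
            d["fixed_effect_levels"] = {
                k: tuple(v) for k, v in d["fixed_effect_levels"].items()
            }
        return cls(**d)


@dataclass
class TraitTruth:
    """Ground truth for one simulated trait."""

    trait: str
    causal_gene_ids: list[str]
    causal_snp_indices: np.ndarray
    causal_effects: np.ndarray  # per causal SNP, standardized-trait units
    sigma2_polygenic: float
    sigma2_causal: float
    sigma2_residual: float
    h2_polygenic_realized: float
    h2_causal_realized: float
    genetic_values: np.ndarray  # g + c on the standardized scale
    residuals: np.ndarray
    fixed_component: np.ndarray
    scale: tuple[float, float]  # (mean, sd) used to place the trait


@dataclass
class SimOutput:
    """Everything the downstream pipeline consumes, plus the ground truth."""

    config: SimConfig
    genotypes: GenotypeMatrix
    genes: list[GeneModel]
    phenotypes: pd.DataFrame  # individual_id + one column per trait
    covariates: pd.DataFrame
    truth: dict[str, TraitTruth]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate additive genotype codes with haplotype-block LD.

    Within each ``ld_block_size`` block the two haplotypes of every
    individual follow the first-order allele-copy process described in the
    module docstring; blocks and chromosomes are independent. Missing
    calls are planted completely at random at ``missing_rate``.
    """
    config.validate()
    rng = config.rng(_STAGE_GENO)
    n = config.n_individuals
    m_chr = config.snps_per_chromosome

    all_codes, snp_ids, chroms, positions = [], [], [], []
    for c in range(1, config.n_chromosomes + 1):
        pos = _snp_positions(rng, m_chr, config.chromosome_length())
        hap = np.empty((2 * n, m_chr), dtype=np.int8)
        lo, hi = config.maf_range
        block_p = 0.0
        for j in range(m_chr):
            if j % config.ld_block_size == 0:
                block_p = rng.uniform(lo, hi)
                hap[:, j] = rng.random(2 * n) < block_p
            else:
                fresh = rng.random(2 * n) < block_p
                copy = rng.random(2 * n) < config.ld_decay
                hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        all_codes.append(hap[:n] + hap[n:])
        snp_ids.extend(f"snp{c}_{j:05d}" for j in range(m_chr))
        chroms.extend([str(c)] * m_chr)
        positions.append(pos)

    codes = np.concatenate(all_codes, axis=1).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(codes.shape) < config.missing_rate
        codes[miss] = MISSING
    return GenotypeMatrix(
        codes=codes,
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.concatenate(positions),
        alleles=np.array([("A", "B")] * codes.shape[1], dtype=object),
        individual_ids=np.array([f"ind{i:05d}" for i in range(config.n_individuals)], dtype=object),
    )


def _snp_positions(rng: np.random.Generator, m: int, length: int) -> np.ndarray:
    """Sorted unique 1-based positions roughly uniform over the chromosome."""
    pos = np.sort(rng.choice(np.arange(1, length + 1), size=m, replace=False))
    return pos.astype(np.int64)


# ---------------------------------------------------------------------------
# gene map
# ---------------------------------------------------------------------------

def simulate_gene_map(config: SimConfig, genotypes: GenotypeMatrix) -> list[GeneModel]:
    """Place ``n_genes`` gene intervals on the simulated chromosomes.

    Raises :class:`ConfigurationError` if fewer than ``n_causal_genes``
    placed genes contain ``causal_snps_per_gene`` SNPs within the standard
    +/-20 kb window — the geometry downstream stages rely on.
    """
    config.validate()
    if config.n_genes == 0:
        return []
    rng = config.rng(_STAGE_GENES)
    chrom_labels = [str(c) for c in range(1, config.n_chromosomes + 1)]
    length = config.chromosome_length()
    glo, ghi = config.gene_length_range
    if ghi >= length:
        raise ConfigurationError(
            f"gene_length_range upper bound {ghi} does not fit on a "
            f"{length} bp chromosome"
        )

    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        chrom = chrom_labels[rng.integers(len(chrom_labels))]
        glen = int(rng.integers(glo, ghi + 1))
        start = int(rng.integers(1, length - glen + 1))
        genes.append(
            GeneModel(
                gene_id=f"SIMG{i:06d}",
                symbol=f"GENE{i}",
                chrom=chrom,
                start_bp=start,
                end_bp=start + glen - 1,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start_bp))

    counts = _window_snp_counts(genotypes, genes, 20_000)
    eligible = int((counts >= config.causal_snps_per_gene).sum())
    if eligible < config.n_causal_genes:
        raise ConfigurationError(
            f"only {eligible} genes carry >= {config.causal_snps_per_gene} SNPs "
            f"in their +/-20 kb window; {config.n_causal_genes} causal genes requested"
        )
    return genes


def _window_snp_counts(
    genotypes: GenotypeMatrix, genes: list[GeneModel], window_bp: int
) -> np.ndarray:
    counts = np.zeros(len(genes), dtype=np.int64)
    for k, gene in enumerate(genes):
        lo, hi = gene.window(window_bp)
        on_chrom = genotypes.chrom == gene.chrom
        counts[k] = int(
            ((genotypes.pos_bp >= lo) & (genotypes.pos_bp <= hi) & on_chrom).sum()
        )
    return counts


def _window_snp_indices(
    genotypes: GenotypeMatrix, gene: GeneModel, window_bp: int
) -> np.ndarray:
    lo, hi = gene.window(window_bp)
    mask = (
        (genotypes.chrom == gene.chrom)
        & (genotypes.pos_bp >= lo)
        & (genotypes.pos_bp <= hi)
    )
    return np.nonzero(mask)[0]


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    config: SimConfig,
    genotypes: GenotypeMatrix,
    genes: list[GeneModel],
    kinship: np.ndarray | None = None,
) -> SimOutput:
    """Simulate covariates and trait values and record the ground truth.

    Each trait in ``config.trait_names`` gets its own causal-gene set
    (sampled among genes with enough window SNPs), its own polygenic and
    residual draws, and the variance fractions from the config. ``kinship``
    lets callers pass a precomputed VanRaden matrix of these genotypes;
    by default it is computed here.
    """
    config.validate()
    rng = config.rng(_STAGE_PHENO)
    n = config.n_individuals
    if genotypes.n_individuals != n:
        raise ConfigurationError(
            f"genotype matrix has {genotypes.n_individuals} individuals, "
            f"config says {config.n_individuals}"
        )

    covariates, fixed = _simulate_covariates(config, rng)

    if kinship is None:
        from .structure import vanraden_grm

        kinship = vanraden_grm(genotypes).values
    # jitter keeps the Cholesky stable when K is rank-deficient (m < n or LD)
    chol = np.linalg.cholesky(kinship + 1e-8 * np.eye(n))

    min_snps = max(config.causal_snps_per_gene, 5)
    counts = _window_snp_counts(genotypes, genes, 20_000)
    eligible = [g for g, c in zip(genes, counts) if c >= min_snps]
    if config.n_causal_genes > 0 and len(eligible) < config.n_causal_genes:
        raise ConfigurationError(
            f"only {len(eligible)} genes have >= {min_snps} window SNPs; "
            f"{config.n_causal_genes} causal genes requested"
        )

    sigma2_e = 1.0 - config.h2_polygenic - config.h2_causal
    dosage = genotypes.dosages(impute=True)

    phenos = pd.DataFrame({"individual_id": genotypes.individual_ids})
    truth: dict[str, TraitTruth] = {}
    for trait in config.trait_names:
        causal = (
            list(rng.choice(len(eligible), size=config.n_causal_genes, replace=False))
            if config.n_causal_genes > 0
            else []
        )
        # each causal gene's summed SNP contribution is scaled to explain
        # h2_causal / n_causal_genes of the genetic-plus-residual variance
        c = np.zeros(n)
        snp_idx_list: list[np.ndarray] = []
        eff_list: list[np.ndarray] = []
        per_gene_h2 = (
            config.h2_causal / config.n_causal_genes if config.n_causal_genes else 0.0
        )
        for gi in causal:
            idx = _window_snp_indices(genotypes, eligible[gi], 20_000)
            idx = np.sort(rng.choice(idx, size=config.causal_snps_per_gene, replace=False))
            signs = rng.choice([-1.0, 1.0], size=len(idx))
            raw = dosage[:, idx] @ signs
            sd = raw.std()
            scale = np.sqrt(per_gene_h2) / sd if (sd > 0 and per_gene_h2 > 0) else 0.0
            snp_idx_list.append(idx)
            eff_list.append(signs * scale)
            c = c + raw * scale
        snp_idx_arr = (
            np.concatenate(snp_idx_list) if snp_idx_list else np.array([], dtype=np.int64)
        )
        effects = np.concatenate(eff_list) if eff_list else np.array([])

        g = np.sqrt(config.h2_polygenic) * (chol @ rng.standard_normal(n))
        e = np.sqrt(sigma2_e) * rng.standard_normal(n)
        y_std = fixed + c + g + e

        mean, sd_scale = TRAIT_SCALES.get(trait, (0.0, 1.0))
        phenos[trait] = mean + sd_scale * y_std

        var_total = g.var() + c.var() + e.var()
        truth[trait] = TraitTruth(
            trait=trait,
            causal_gene_ids=[eligible[gi].gene_id for gi in causal],
            causal_snp_indices=snp_idx_arr,
            causal_effects=effects,
            sigma2_polygenic=config.h2_polygenic,
            sigma2_causal=config.h2_causal,
            sigma2_residual=sigma2_e,
            h2_polygenic_realized=float(g.var() / var_total),
            h2_causal_realized=float(c.var() / var_total),
            genetic_values=g + c,
            residuals=e,
            fixed_component=fixed,
            scale=(mean, sd_scale),
        )
        logger.info(
            "trait %s: causal genes %s, realized h2_poly=%.3f h2_causal=%.3f",
            trait,
            truth[trait].causal_gene_ids,
            truth[trait].h2_polygenic_realized,
            truth[trait].h2_causal_realized,
        )

    return SimOutput(
        config=config,
        genotypes=genotypes,
        genes=genes,
        phenotypes=phenos,
        covariates=covariates,
        truth=truth,
    )


def _simulate_covariates(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw the covariate table and its summed fixed-effect contribution
    (standardized-trait units)."""
    n = config.n_individuals
    cov = pd.DataFrame(
        {"individual_id": [f"ind{i:05d}" for i in range(n)]}
    )
    fixed = np.zeros(n)
    for name, (n_levels, sd) in config.fixed_effect_levels.items():
        levels = rng.integers(n_levels, size=n)
        effects = rng.normal(0.0, sd, size=n_levels)
        cov[name] = np.array([f"{name}{v}" for v in levels], dtype=object)
        fixed += effects[levels]
    cont_params = {"fattening_days": (160.0, 20.0), "entering_weight": (250.0, 30.0)}
    for name, beta in config.continuous_effects.items():
        mu, sd = cont_params.get(name, (0.0, 1.0))
        x = rng.normal(mu, sd, size=n)
        cov[name] = x
        fixed += beta * (x - mu) / sd
    return cov, fixed


def simulate(config: SimConfig) -> SimOutput:
    """Run all three stages: genotypes, gene map, covariates + phenotypes."""
    genotypes = simulate_genotypes(config)
    genes = simulate_gene_map(config, genotypes)
    return simulate_phenotypes(config, genotypes, genes)
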