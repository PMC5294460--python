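# Methods

## The two-stage gene-based test

A gene's evidence is aggregated over all SNPs mapped to it. Stage 1
computes the variance–covariance matrix of the gene's mean-imputed,
centered genotype codes and eigendecomposes it; the smallest number
`K` of leading components whose cumulative eigenvalue fraction reaches
the variance target (default 0.85) is retained, and PC scores are the
centered genotype matrix times those eigenvectors. Stage 2 tests each
PC against the adjusted trait through its Pearson correlation,
converted to a two-sided p-value via `t = r√(n−2)/√(1−r²)` on `n−2`
df, and combines the `K` p-values with Fisher's statistic
`χ² = −2Σ ln p_k ~ χ²(2K)` under the null. The χ² reference is
licensed by the exact orthogonality of the PC scores (asserted in the
test suite to 1e−8). Genome-wide significance is Bonferroni over the
genes actually tested.

Assumptions worth keeping in view: per-PC tests assume an
approximately normal trait after fixed-effect adjustment;
independence of the K p-values holds exactly only under joint
normality of scores and trait; and the polygenic background is *not*
modelled in stage 2 (see Limitations).

Numerical choices: covariance (not correlation) PCA of the genotype
codes, with a documented switch unnecessary for the default pipeline;
`K` chosen as the smallest count with cumulative fraction ≥ target,
ties broken by the deterministic eigensolver order; PC signs fixed by
making the largest-magnitude loading positive; zero-variance SNP
columns dropped with a log entry and a fully degenerate gene skipped;
p-values of exactly 0 (t-distribution underflow) clamped to 1e−300
before logging, which keeps χ² finite and cannot change any ranking;
two-sided per-PC tests, since PC orientation is arbitrary.

## Supporting pipeline

**QC** (defaults): individual missingness ≤ 10% first; then per-SNP
filters on the retained individuals in a fixed order — unmapped
position, call rate ≥ 0.90, MAF ≥ 0.05, minimum genotype-class count
≥ 5, HWE exact-test p ≥ 1e−6 — with each removed SNP attributed to
the first filter that caught it. The genotype-count rule is read as
"least frequent observed genotype class", recorded in the report; a
class with zero carriers is left to the MAF filter. The HWE test is
the standard exact formulation (no mid-p), conditioning on allele
counts and summing probabilities of heterozygote counts no more
likely than the observed one; the recurrence is anchored at the modal
count so neither tail under/overflows. A pedigree-based Mendelian
error filter is exposed as an explicit no-op hook: the package does
not model pedigrees.

**Kinship and structure.** VanRaden's first estimator
`G = ZZᵀ/(2Σp_j(1−p_j))`, centering at twice the observed allele
frequency after per-SNP mean imputation (the standard chip
convention; imputation and centering choices are stated in the output
metadata). Structure PCs come from a seeded random fraction of
markers (default 10%, 5 components) via SVD of the centered dosage
matrix, observed-mean centering.

**Adjustment.** OLS of each trait on intercept, dummy-coded year /
farm / gender, continuous fattening days and entering weight, and the
structure PCs. Incomplete rows are dropped with a logged count;
rank-deficient designs raise an error naming the aliased columns
(QR with column pivoting); constant covariates are dropped as
intercept duplicates. Residuals are invariant to the dummy reference
level.

**Gene mapping.** A SNP maps to a gene when its position falls in the
closed interval `[start − 20 kb, end + 20 kb]`; a SNP at exactly the
window edge is included (both boundaries are unit-tested). Genes with
fewer than 5 mapped SNPs are dropped with a count. A SNP may belong
to several overlapping genes; no deduplication is attempted, so
overlapping genes are tested with shared evidence (visible in the
README example). Annotation is normalized to 1-based inclusive
coordinates; BED input is converted on read. Nearest-gene annotation
reports "in" inside a gene body, otherwise the bp distance to the
nearer edge.

**Mixed-model scan.** `Y = Xβ + Wv + Zμ + e` with `μ ~ N(0, σ²_g K)`
at the individual level (`Z = I`; no compression of individuals into
groups — stated in the result metadata). Variance components are
estimated once on the null model by REML, parametrized by
heritability `h` with the total variance profiled out, maximized by
bounded scalar search on the data rotated by the eigenvectors of `K`;
the same rotation turns each per-SNP GLS fit into weighted OLS. The
t-test uses `n − rank(X) − 1` df. A boundary estimate `σ²_g ≈ 0`
warns and the scan degrades gracefully to OLS.

## The synthetic study

The generator emulates the statistical structure the analysis
assumes, at desk scale. Defaults: n = 1,000 diploid individuals; 5
chromosomes × 2,000 SNPs at ~3 kb mean spacing; haplotype blocks of
10 SNPs sharing one allele frequency drawn from U(0.05, 0.5); within
a block each haplotype allele copies its left neighbour with
probability `ld_decay` = 0.7 (a first-order process whose target
adjacent-SNP genotype correlation is exactly `ld_decay`, verified
against the realized correlation in the tests) — adjacent-marker LD
of that order is realistic for a dense bovine panel; independent
blocks; 500 genes of 5–50 kb; missingness 2% completely at random.

Traits are built on a standardized scale as
`y* = fixed effects + c + g + e`: categorical year (3 levels), farm
(5), gender (2) with level effects ~ N(0, 0.3²); continuous fattening
days and entering weight with standardized slopes 0.2; polygenic
`g ~ N(0, h²_poly K)` drawn through the Cholesky factor of the
VanRaden kinship of the simulated genotypes themselves (which makes
REML recovery well-posed); each of the `n_causal_genes` (default 3)
contributes `causal_snps_per_gene` (default 2) random-signed SNP
effects from its ±20 kb window, scaled so the gene explains
`h²_causal / n_causal_genes` of the genetic-plus-residual variance;
`e` fills the remainder. Defaults `h²_poly = 0.41` (a bone-weight-like
trait) and `h²_causal = 0.06` (2% per causal gene). The emitted trait
is `mean + sd·y*` with BW-like (40, 6.58) and pH-like (5.63, 0.38)
location/scale. Two traits are generated per study, sharing the
variance fractions but with independent causal-gene sets and draws.
One master seed spawns per-stage generators so genotypes, gene map
and phenotypes can be regenerated independently; everything is
bitwise reproducible under a fixed seed.

What the generator does **not** emulate: realistic recombination maps
or long-range LD decay, selection, pedigree/family structure, sex
chromosomes, covariate–genotype correlation (farms are independent of
ancestry, unlike real cohorts), or genotyping-error patterns. Passing
tests therefore demonstrate correctness and calibration of the
machinery under exchangeable-individual, block-LD conditions — not
performance on a structured real population.

## Monte Carlo problem sizes

The calibration and recovery suites simulate one genotype panel and
redraw phenotypes per replicate (the panel-conditional error and
power rates are the quantities of interest, and this keeps the suite
fast): null calibration at n = 500, 6,000 SNPs, 1,000 genes, 200
scan replicates; causal-gene recovery at n = 1,000, 500 genes, 50
replicates; heritability recovery at n = 1,000 with 200 REML
replicates on a fixed kinship. `scripts/acceptance.py` repeats these
at 100 / 25 / 100 replicates.

## Calibration notes

- With a *no-genetic-signal* null (fixed effects only), the gene scan
  is well calibrated: family-wise error at the Bonferroni level ≲
  0.02, pooled λ_GC ≈ 1.01, and per-gene p-values uniform by KS on an
  independent subsample. At very large pooled samples (~2×10⁵) a KS
  test resolves a real ≈2% ECDF deviation: stage 2 correlates PCs
  with OLS *residuals* (effective df n−q) but refers t to n−2 df, as
  the method is published. The effect is negligible at any practical
  significance level.
- Under a purely polygenic null (h² = 0.41, no causal genes) the gene
  test is mildly *inflated*: five structure PCs cannot absorb
  genome-wide relatedness, so every gene weakly tags the polygenic
  signal. This is inherent to fixed-effect gene tests on
  PC-adjusted residuals; a kinship-aware stage 2 would be the remedy
  and is out of scope.

## Limitations

- **Minor-direction blindness.** The 85% truncation discards
  low-variance PC directions. A causal contrast that lives there —
  the worst case being opposite-signed causal SNPs within one LD
  block, whose difference is a minor component — is largely invisible
  to the test. In the recovery suite (three 2%-variance causal genes,
  two random-signed causal SNPs each, block LD 0.7, polygenic
  background 0.41) all three causal genes land in the top 10 of ~500
  genes in well under half of replicates, even though an OLS oracle
  on the true causal design recovers the signal every time; the
  per-gene top-10 rate is ~0.4–0.6. Aligned-effect or
  single-causal-SNP genes are recovered far more reliably. This is a
  property of the statistic, not of the implementation.
- Genes overlapping a true signal's window co-fire (shared SNPs);
  multiplicity is counted per gene with no window-overlap correction,
  matching standard practice.
- The mixed model uses P3D (null-model variance components reused per
  SNP) and individual-level random effects; exact per-SNP REML and
  group compression are not implemented.
- The HWE exact test assumes autosomal biallelic markers; X-linked
  markers are out of scope.
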