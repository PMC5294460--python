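"""The two-stage gene-based test: within-gene PCA against independent
eigensolvers and analytic spectra, correlation-t p-values against a
numerical-integration oracle, Fisher's combination against closed
forms, and calibration under the null."""

import math

import numpy as np
import pytest
import scipy.integrate
import scipy.stats

from genegwas import (
    DegenerateInputError,
    assign_snps_to_genes,
    bonferroni_threshold,
    fisher_combination,
    gene_pca,
    genome_scan,
    pc_pvalues,
    precompute_gene_pcs,
    scan_decompositions,
)
from genegwas.genetest import GenePcDecomposition

from conftest import make_genotype_matrix


# ---------------------------------------------------------------------------
# Stage 1: within-gene PCA
# ---------------------------------------------------------------------------

def test_rank_one_gene_single_pc(rng):
    col = rng.choice([0, 1, 2], size=(50, 1))
    g = make_genotype_matrix(np.repeat(col, 5, axis=1))
    dec = gene_pca(g, np.arange(5))
    assert dec.k == 1
    assert dec.variance_fraction_captured == pytest.approx(1.0)


def test_flat_spectrum_k_near_analytic(rng):
    """Independent equal-variance SNPs have a flat covariance spectrum,
    so the 85% rule keeps about ceil(0.85 * m) components."""
    m, n = 20, 4000
    codes = rng.binomial(2, 0.3, size=(n, m))
    dec = gene_pca(make_genotype_matrix(codes), np.arange(m))
    assert abs(dec.k - math.ceil(0.85 * m)) <= 1


def _jacobi_eig(a, sweeps=100):
    """Independent symmetric eigensolver (cyclic Jacobi rotations)."""
    a = a.copy().astype(float)
    n = a.shape[0]
    v = np.eye(n)
    for _ in range(sweeps):
        off = np.sqrt(np.sum(np.tril(a, -1) ** 2))
        if off < 1e-14:
            break
        for p in range(n - 1):
            for q in range(p + 1, n):
                if abs(a[p, q]) < 1e-300:
                    continue
                theta = 0.5 * math.atan2(2 * a[p, q], a[q, q] - a[p, p])
                c, s = math.cos(theta), math.sin(theta)
                rot = np.eye(n)
                rot[p, p] = rot[q, q] = c
                rot[p, q] = s
                rot[q, p] = -s
                a = rot.T @ a @ rot
                v = v @ rot
    return np.diag(a), v


def test_gene_pca_matches_independent_eigensolver(rng):
    """K and the retained scores from a 6-SNP gene agree with a
    from-scratch Jacobi eigendecomposition of the same covariance."""
    codes = rng.choice([0, 1, 2], size=(40, 6), p=[0.25, 0.5, 0.25])
    codes[:, 3] = np.clip(codes[:, 2] + rng.choice([0, 0, 1], size=40), 0, 2)
    g = make_genotype_matrix(codes)
    dec = gene_pca(g, np.arange(6))

    x = codes.astype(float)
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (len(x) - 1)
    vals, vecs = _jacobi_eig(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    assert np.allclose(np.sort(dec.eigenvalues), np.sort(vals), atol=1e-8)
    k_oracle = int(np.searchsorted(np.cumsum(vals) / vals.sum(), 0.85 - 1e-12) + 1)
    assert dec.k == k_oracle
    for j in range(dec.k):
        score_oracle = xc @ vecs[:, j]
        same = np.allclose(dec.pc_scores[:, j], score_oracle, atol=1e-6)
        flipped = np.allclose(dec.pc_scores[:, j], -score_oracle, atol=1e-6)
        assert same or flipped


def test_variance_bookkeeping_and_orthogonality(small_sim):
    asg = assign_snps_to_genes(small_sim.genotypes, small_sim.genes)
    gid = next(iter(asg.snp_indices))
    dec = gene_pca(small_sim.genotypes, asg.snp_indices[gid], gene_id=gid)
    x = small_sim.genotypes.subset(snps=asg.snp_indices[gid]).dosages()
    xc = x - x.mean(axis=0)
    trace = np.trace(xc.T @ xc / (len(x) - 1))
    assert dec.eigenvalues.sum() == pytest.approx(trace, rel=1e-8)
    # the retained PCs are uncorrelated: this is what licenses the
    # 2K-df chi-square reference distribution for Fisher's statistic
    corr = np.corrcoef(dec.pc_scores.T)
    assert np.allclose(corr, np.eye(dec.k), atol=1e-8)


def test_zero_variance_columns_dropped_and_degenerate_error():
    codes = np.zeros((30, 3), dtype=np.int8)
    codes[:, 0] = np.arange(30) % 3
    g = make_genotype_matrix(codes)
    dec = gene_pca(g, np.arange(3))
    assert dec.n_dropped_zero_variance == 2
    with pytest.raises(DegenerateInputError):
        gene_pca(g, np.array([1, 2]))


# ---------------------------------------------------------------------------
# Stage 2: per-PC p-values
# ---------------------------------------------------------------------------

def _t_sf_by_quadrature(t, df):
    """Upper-tail t probability by numerical integration of the density."""
    const = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    dens = lambda u: const * (1 + u * u / df) ** (-(df + 1) / 2)
    val, _ = scipy.integrate.quad(dens, t, np.inf)
    return val


def test_pc_pvalue_matches_quadrature_oracle():
    n, r = 20, 0.5
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    expected = 2 * _t_sf_by_quadrature(t, n - 2)
    # build scores/phenotype with exactly this correlation
    x = np.arange(n, dtype=float)
    x = (x - x.mean()) / x.std()
    z = np.zeros(n)
    z[0], z[1] = 1.0, -1.0
    z = z - (z @ x) / (x @ x) * x  # orthogonalize
    z /= z.std()
    y = r * x + math.sqrt(1 - r * r) * z
    dec = GenePcDecomposition(gene_id="t", pc_scores=x[:, None],
                              eigenvalues=np.array([1.0]),
                              variance_fraction_captured=1.0, k=1, n_snps=1)
    p = pc_pvalues(dec, y)
    assert p[0] == pytest.approx(expected, rel=1e-8)


def test_pc_pvalue_zero_correlation_gives_one():
    x = np.tile([1.0, -1.0], 20)
    y = np.tile([1.0, 1.0, -1.0, -1.0], 10)  # exactly uncorrelated with x
    dec = GenePcDecomposition(gene_id="t", pc_scores=x[:, None],
                              eigenvalues=np.array([1.0]),
                              variance_fraction_captured=1.0, k=1, n_snps=1)
    assert pc_pvalues(dec, y)[0] == pytest.approx(1.0)


def test_pc_pvalues_uniform_under_null(small_sim):
    """With a trait independent of the genotypes, per-PC p-values are
    uniform on (0,1)."""
    asg = assign_snps_to_genes(small_sim.genotypes, small_sim.genes)
    gid = next(iter(asg.snp_indices))
    dec = gene_pca(small_sim.genotypes, asg.snp_indices[gid], gene_id=gid)
    null_rng = np.random.default_rng(7)
    n = small_sim.genotypes.n_individuals
    ps = np.concatenate([
        pc_pvalues(dec, null_rng.standard_normal(n)) for _ in range(10_000 // dec.k + 1)
    ])
    assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# Fisher's combination
# ---------------------------------------------------------------------------

def test_fisher_single_p_is_identity():
    for p1 in (1.0, 0.7, 0.05, 1e-10):
        chi2, df, gene_p = fisher_combination(np.array([p1]))
        assert df == 2
        assert gene_p == pytest.approx(p1, rel=1e-12)
    chi2, df, gene_p = fisher_combination(np.array([1.0]))
    assert chi2 == 0.0 and gene_p == 1.0


def test_fisher_df4_closed_form_oracle():
    """For K=2 the chi-square survival function has the closed form
    exp(-x/2) * (1 + x/2)."""
    chi2, df, gene_p = fisher_combination(np.array([0.05, 0.05]))
    assert df == 4
    assert chi2 == pytest.approx(-4.0 * math.log(0.05), rel=1e-12)
    assert gene_p == pytest.approx(math.exp(-chi2 / 2) * (1 + chi2 / 2), rel=1e-12)


def test_fisher_monotone_in_each_component(rng):
    """Decreasing any single p-value never increases the combined p."""
    for _ in range(1000):
        k = int(rng.integers(1, 8))
        p = rng.uniform(1e-12, 1.0, size=k)
        _, _, base = fisher_combination(p)
        j = int(rng.integers(k))
        q = p.copy()
        q[j] *= rng.uniform(0.0, 1.0)
        q[j] = max(q[j], 1e-300)
        _, _, lower = fisher_combination(q)
        assert lower <= base + 1e-15


def test_fisher_domain_handling():
    with pytest.raises(DegenerateInputError):
        fisher_combination(np.array([0.5, 1.2]))
    with pytest.raises(DegenerateInputError):
        fisher_combination(np.array([-0.1]))
    with pytest.warns(UserWarning):
        chi2, df, gene_p = fisher_combination(np.array([0.0, 0.5]))
    assert np.isfinite(chi2) and gene_p >= 0.0


def test_fisher_extreme_underflow_stays_finite():
    chi2, df, gene_p = fisher_combination(np.array([1e-300, 1e-250]))
    assert np.isfinite(chi2)
    assert 0.0 <= gene_p < 1e-200


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def test_bonferroni_threshold_arithmetic():
    assert bonferroni_threshold(21836) == pytest.approx(2.29e-6, rel=5e-3)
    assert bonferroni_threshold(10, alpha=0.05) == pytest.approx(0.005)


def test_genome_scan_empty_assignment_raises(small_sim):
    from genegwas.genemap import GeneSnpAssignment

    empty = GeneSnpAssignment(snp_indices={}, genes={}, window_bp=20000, min_snps=5)
    with pytest.raises(DegenerateInputError):
        genome_scan(small_sim.genotypes, empty, np.zeros(300))


def test_genome_scan_results_sorted_and_flagged(small_sim):
    asg = assign_snps_to_genes(small_sim.genotypes, small_sim.genes)
    null_rng = np.random.default_rng(5)
    res = genome_scan(small_sim.genotypes, asg,
                      null_rng.standard_normal(small_sim.genotypes.n_individuals))
    keys = [(r.chrom, r.start_bp) for r in res]
    assert keys == sorted(keys)
    thr = bonferroni_threshold(len(res))
    for r in res:
        assert r.df == 2 * r.k
        assert 0 < r.gene_p <= 1
        assert r.significant == (r.gene_p < thr)


def test_gene_p_uniform_under_phenotype_permutation(small_sim):
    """Permuting the phenotype breaks any genotype association, so the
    gene p for a fixed gene must be uniform across permutations."""
    asg = assign_snps_to_genes(small_sim.genotypes, small_sim.genes)
    decs = precompute_gene_pcs(small_sim.genotypes, asg)
    gid = next(iter(decs))
    dec = decs[gid]
    perm_rng = np.random.default_rng(11)
    y = small_sim.phenotypes["BW"].to_numpy()
    ps = []
    for _ in range(2000):
        yp = perm_rng.permutation(y)
        p_k = pc_pvalues(dec, yp)
        ps.append(fisher_combination(p_k)[2])
    assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01


def test_scan_decompositions_matches_full_scan(small_sim):
    asg = assign_snps_to_genes(small_sim.genotypes, small_sim.genes)
    y = small_sim.phenotypes["BW"].to_numpy()
    full = genome_scan(small_sim.genotypes, asg, y)
    decs = precompute_gene_pcs(small_sim.genotypes, asg)
    fast = scan_decompositions(decs, asg, y)
    assert [r.gene_id for r in full] == [r.gene_id for r in fast]
    assert np.allclose([r.gene_p for r in full], [r.gene_p for r in fast])
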