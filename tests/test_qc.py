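"""Quality-control filters checked against independent oracles: explicit
count loops for call rate, full enumeration for the HWE exact test, and
one-rule-at-a-time re-application for the combined filter."""

import math

import numpy as np
import pytest

from genegwas import DegenerateInputError, apply_qc, hwe_exact_test, hwe_test, minor_allele_frequency, snp_call_rate
from genegwas.qc import QcThresholds, genotype_counts, individual_call_rate, mendel_error_filter

from conftest import make_genotype_matrix


# ---------------------------------------------------------------------------
# call rate and MAF
# ---------------------------------------------------------------------------

def test_call_rate_simple_cases():
    g = make_genotype_matrix(np.zeros((10, 2)))
    assert np.allclose(snp_call_rate(g), 1.0)
    codes = np.zeros((10, 1), dtype=np.int8)
    codes[:3, 0] = -1
    assert snp_call_rate(make_genotype_matrix(codes))[0] == pytest.approx(0.7)


def test_call_rate_matches_explicit_loop(rng):
    codes = rng.choice([0, 1, 2, -1], size=(40, 25), p=[0.3, 0.3, 0.3, 0.1])
    g = make_genotype_matrix(codes)
    expected = [np.mean(codes[:, j] != -1) for j in range(25)]
    assert np.allclose(snp_call_rate(g), expected)
    expected_ind = [np.mean(codes[i] != -1) for i in range(40)]
    assert np.allclose(individual_call_rate(g), expected_ind)


def test_maf_arithmetic_and_orientation(rng):
    g = make_genotype_matrix(np.array([[0], [0], [0], [0]]))
    assert minor_allele_frequency(g)[0] == 0.0
    g = make_genotype_matrix(np.array([[0], [1], [1], [2]]))
    assert minor_allele_frequency(g)[0] == pytest.approx(0.5)
    # counted-allele frequency 0.75 folds to 0.25
    g = make_genotype_matrix(np.array([[2], [2], [1], [1]]))
    assert minor_allele_frequency(g)[0] == pytest.approx(0.25)
    # property: always <= 0.5
    codes = rng.choice([0, 1, 2, -1], size=(60, 30), p=[0.1, 0.2, 0.6, 0.1])
    maf = minor_allele_frequency(make_genotype_matrix(codes))
    assert np.all(maf[~np.isnan(maf)] <= 0.5 + 1e-12)


def test_maf_report_precision():
    # hit tables report MAF to four decimals, e.g. 0.3623
    assert f"{0.36234:.4f}" == "0.3623"


# ---------------------------------------------------------------------------
# HWE exact test vs enumeration oracle
# ---------------------------------------------------------------------------

def _hwe_enumeration_oracle(n_hom_minor, n_het, n_hom_major):
    """Exact HWE p by explicit enumeration of every heterozygote count
    using log-factorial probabilities (independent of the recurrence
    implementation)."""
    n = n_hom_minor + n_het + n_hom_major
    na = 2 * n_hom_minor + n_het  # minor allele count
    if na > n:
        na = 2 * n - na
    if n == 0 or na == 0:
        return 1.0

    def log_prob(h):
        hom_r = (na - h) // 2
        hom_c = n - h - hom_r
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_r + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_c + 1)
            + h * math.log(2)
            + math.lgamma(na + 1)
            + math.lgamma(2 * n - na + 1)
            - math.lgamma(2 * n + 1)
        )

    hs = list(range(na % 2, na + 1, 2))
    probs = {h: math.exp(log_prob(h)) for h in hs}
    p_obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


@pytest.mark.parametrize(
    "counts",
    [
        (25, 50, 25),   # perfect HWE
        (50, 0, 50),    # extreme heterozygote deficit
        (0, 100, 0),    # extreme heterozygote excess
        (3, 17, 80),
        (1, 1, 98),
        (10, 20, 170),
        (0, 5, 95),
    ],
)
def test_hwe_matches_enumeration_oracle(counts):
    assert hwe_exact_test(*counts) == pytest.approx(
        _hwe_enumeration_oracle(*counts), rel=1e-10
    )


def test_hwe_qualitative_behavior():
    assert hwe_exact_test(25, 50, 25) > 0.9          # perfect proportions
    assert hwe_exact_test(50, 0, 50) < 1e-6          # severe departure
    assert hwe_exact_test(0, 0, 100) == 1.0          # monomorphic convention
    g = make_genotype_matrix(np.array([[0], [0], [0]]))
    assert hwe_test(g)[0] == 1.0


# ---------------------------------------------------------------------------
# combined filter
# ---------------------------------------------------------------------------

def _planted_matrix(rng):
    """100 individuals, 60 clean SNPs plus one violation of each filter:
    column 60 low call rate, 61 rare, 62 thin genotype class, 63 HWE
    departure, 64 unmapped position. Individual 0 is fully missing."""
    n = 100
    codes = rng.choice([0, 1, 2], size=(n, 65), p=[0.36, 0.48, 0.16]).astype(np.int8)
    codes[:40, 60] = -1                      # call rate 0.6 < 0.9
    codes[:, 61] = 0
    codes[1, 61] = 1                         # MAF ~ 1/200 < 0.05
    codes[:, 62] = np.array([2] * 5 + [1] * 48 + [0] * 47)  # minor class -> 4 after ind drop
    codes[:, 63] = np.array([0] * 50 + [2] * 50)            # het deficit, HWE p ~ 0
    pos = np.arange(1, 66) * 1000
    pos[64] = 0                              # unmapped
    codes[0, :] = -1                         # individual 0: 100% missing
    return make_genotype_matrix(codes, pos=pos)


def test_apply_qc_clean_matrix_is_identity(small_sim):
    clean, report = apply_qc(small_sim.genotypes)
    again, report2 = apply_qc(clean)
    # idempotence: the second pass removes nothing
    assert again.codes.shape == clean.codes.shape
    assert report2.removed_individuals_missingness == 0
    assert all(v == 0 for v in report2.removed_snps.values())


def test_apply_qc_attributes_each_planted_violation(rng):
    g = _planted_matrix(rng)
    out, report = apply_qc(g)
    assert report.removed_individuals_missingness == 1
    assert report.removed_snps == {
        "unmapped": 1, "call_rate": 1, "maf": 1, "genotype_count": 1, "hwe": 1,
    }
    assert out.n_snps == 60
    assert set(out.snp_ids) == {f"s{j}" for j in range(60)}
    assert report.n_snps_in - sum(report.removed_snps.values()) == report.n_snps_out


def test_apply_qc_matches_independent_rule_oracle(rng):
    """Surviving SNP set equals the intersection of each rule applied
    independently (after the individual filter)."""
    codes = rng.choice([0, 1, 2, -1], size=(120, 80), p=[0.3, 0.25, 0.33, 0.12])
    g = make_genotype_matrix(codes)
    thr = QcThresholds()
    out, _ = apply_qc(g, thr)

    keep_ind = individual_call_rate(g) >= 1 - thr.max_individual_missing
    g2 = g.subset(individuals=keep_ind)
    rules = (
        snp_call_rate(g2) >= thr.min_call_rate,
        np.nan_to_num(minor_allele_frequency(g2), nan=-1) >= thr.min_maf,
        _min_class_ok(g2, thr.min_genotype_count),
        hwe_test(g2) >= thr.min_hwe_p,
    )
    expected = set(g2.snp_ids[np.logical_and.reduce(rules)])
    assert set(out.snp_ids) == expected


def _min_class_ok(g, min_count):
    counts = genotype_counts(g)
    ok = np.ones(g.n_snps, dtype=bool)
    for j in range(g.n_snps):
        present = counts[j][counts[j] > 0]
        if len(present) > 1 and present.min() < min_count:
            ok[j] = False
    return ok


def test_surviving_snps_pass_every_threshold(small_sim):
    thr = QcThresholds()
    out, _ = apply_qc(small_sim.genotypes, thr)
    assert np.all(snp_call_rate(out) >= thr.min_call_rate)
    assert np.all(minor_allele_frequency(out) >= thr.min_maf)
    assert np.all(hwe_test(out) >= thr.min_hwe_p)
    assert np.all(_min_class_ok(out, thr.min_genotype_count))


def test_all_removed_raises():
    g = make_genotype_matrix(np.zeros((20, 3)))  # all monomorphic -> MAF filter
    with pytest.raises(DegenerateInputError):
        apply_qc(g)


def test_mendel_hook_is_noop_without_pedigree(small_sim):
    g = mendel_error_filter(small_sim.genotypes)
    assert g is small_sim.genotypes
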