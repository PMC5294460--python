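import numpy as np
import pytest

from genegwas import GenotypeMatrix, SimConfig, simulate


def make_genotype_matrix(codes, chrom=None, pos=None, snp_ids=None, ids=None):
    """Wrap a raw code array in a GenotypeMatrix with simple metadata."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    return GenotypeMatrix(
        codes=codes,
        snp_ids=np.array(snp_ids if snp_ids is not None else [f"s{j}" for j in range(m)], dtype=object),
        chrom=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos_bp=np.array(pos if pos is not None else np.arange(1, m + 1) * 1000, dtype=np.int64),
        alleles=np.array([("A", "B")] * m, dtype=object),
        individual_ids=np.array(ids if ids is not None else [f"i{i}" for i in range(n)], dtype=object),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A compact but complete synthetic study reused across test modules."""
    cfg = SimConfig(
        n_individuals=300,
        n_chromosomes=2,
        snps_per_chromosome=500,
        n_genes=60,
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
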