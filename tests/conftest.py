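import numpy as np
import pytest

from sweepkit.simulate import SimParams, SweepSettings, simulate, write_fixture
from sweepkit.variant_io import GenotypeMatrix


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic two-population neutral simulation."""
    params = SimParams(n_anc=40, pop_sizes=(40, 40), split_gens=(15, 15),
                       n_sample=8, seq_len=250_000, mu=6e-6, rec=6e-6,
                       seed=20260926, burn_in=300, pop_names=("TC", "BI"))
    return simulate(params)


@pytest.fixture(scope="session")
def small_fixture_dir(small_sim, tmp_path_factory):
    """VCF / popmap / GFF3 / truth files for the small simulation."""
    out = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(small_sim, out)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_genotype_matrix(rng, n_sites=30, n_samples=12, missing_rate=0.0,
                           chrom="chr1", phased=True, chrom_length=None):
    """Small random matrix with consistent genotype/phase encoding."""
    phase = rng.integers(0, 2, size=(n_sites, 2 * n_samples)).astype(np.int8)
    genotypes = (phase[:, 0::2] + phase[:, 1::2]).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random((n_sites, n_samples)) < missing_rate
        genotypes[miss] = -1
        phase[np.repeat(miss, 2, axis=1)] = -1
    positions = np.sort(rng.choice(np.arange(1, 20 * n_sites + 1), size=n_sites,
                                   replace=False))
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_sites)]
    alt = bases[(np.searchsorted(bases, ref) + rng.integers(1, 4, n_sites)) % 4]
    return GenotypeMatrix(chrom=chrom, positions=positions, ref=ref, alt=alt,
                          genotypes=genotypes, samples=[f"s{i}" for i in range(n_samples)],
                          phase=None if not phased else phase,
                          chrom_length=chrom_length or int(positions[-1]) + 10)
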