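import numpy as np
import pytest

from pclmhap import SimulationSpec, aggregate_genotypes, simulate_population
from pclmhap.estimator import _allele_freqs_from_counts
from pclmhap.pclm_core import linkage_equilibrium_prior


@pytest.fixture(scope="session")
def two_snp_freqs():
    """Two-SNP haplotype pool with real linkage disequilibrium."""
    return np.array([0.4, 0.1, 0.2, 0.3])


@pytest.fixture(scope="session")
def two_snp_counts(two_snp_freqs):
    """Genotype counts from 500 individuals of the two-SNP pool (seed 1)."""
    g = simulate_population(SimulationSpec(2, two_snp_freqs, 500, seed=1))
    return aggregate_genotypes(g)


@pytest.fixture(scope="session")
def two_snp_genotypes(two_snp_freqs):
    return simulate_population(SimulationSpec(2, two_snp_freqs, 500, seed=1))


@pytest.fixture(scope="session")
def four_hap_panel():
    """4-SNP panel with four true haplotypes at (0.4, 0.3, 0.2, 0.1)."""
    p = np.zeros(16)
    p[[0b0000, 0b0101, 0b1010, 0b1111]] = [0.4, 0.3, 0.2, 0.1]
    g = simulate_population(SimulationSpec(4, p, 1000, seed=1))
    return p, g


def le_prior_from_counts(counts, n_snps):
    return linkage_equilibrium_prior(_allele_freqs_from_counts(counts, n_snps))
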