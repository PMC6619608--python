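import numpy as np
import pytest

from orgvar.io import GenomeAlignment, SnpMatrix
from orgvar.simulate import SimConfig, simulate_alignment_set, simulate_mito_matrix


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down study: 19 samples, 8 kb genome, fewer planted events."""
    return SimConfig(seed=7, genome_length=8000, n_snp=20, n_indel=3,
                     n_homopolymer=4, n_inversion=1, n_diagnostic=4,
                     n_mito_sites=40)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_alignment_set(small_config)


@pytest.fixture(scope="session")
def default_sim():
    """One study-scale simulation (19 samples, 20 kb, 84/5/17/1 events)."""
    return simulate_alignment_set(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_mito(small_config):
    return simulate_mito_matrix(small_config)


@pytest.fixture()
def tiny_alignment() -> GenomeAlignment:
    rows = {
        "ref":  "ACGTACGTAC",
        "s2":   "ACGTACGTAC",
        "s3":   "ACGTACGTAC",
    }
    return GenomeAlignment(sample_ids=list(rows), rows=rows, reference_id="ref")


def random_snp_matrix(rng: np.random.Generator, n_sites: int, n_samples: int,
                      missing_rate: float = 0.2) -> SnpMatrix:
    """A random biallelic matrix whose sites keep >= 2 observed states."""
    bases = np.array(list("ACGT"))
    alleles = np.empty((n_sites, n_samples), dtype="U1")
    for i in range(n_sites):
        a, b = rng.choice(4, size=2, replace=False)
        row = np.where(rng.random(n_samples) < 0.5, bases[a], bases[b])
        # guarantee both states present
        row[0], row[1] = bases[a], bases[b]
        mask = rng.random(n_samples) < missing_rate
        mask[:2] = False
        row = row.astype("U1")
        row[mask] = "?"
        alleles[i] = row
    return SnpMatrix(site_ids=[f"s{i}" for i in range(n_sites)],
                     sample_ids=[f"ind{j}" for j in range(n_samples)],
                     alleles=alleles)
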