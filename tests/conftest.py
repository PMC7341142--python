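import numpy as np
import pandas as pd
import pytest

from dhdrift import SimulationConfig, simulate_accession
from dhdrift.genotype_io import GenotypeMatrix


@pytest.fixture(scope="session")
def small_sim():
    """A neutral simulated accession reused by read-only tests."""
    return simulate_accession(
        SimulationConfig(n_sites=300, n_lr_individuals=15, n_dh_lines=30, n_H=60, seed=11)
    )


def make_matrix(dosages, positions=None, chrom="1", samples=None, haplotypes=None):
    """Build a GenotypeMatrix from a plain dosage array for unit tests."""
    dosages = np.asarray(dosages, dtype=np.int16)
    n_samples, n_sites = dosages.shape
    if positions is None:
        positions = 1 + 100 * np.arange(n_sites)
    if samples is None:
        samples = [f"S{i}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "site_id": [f"{chrom}_{p}" for p in positions],
        }
    )
    return GenotypeMatrix(samples, sites, dosages, haplotypes)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
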