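import numpy as np
import pandas as pd
import pytest

from popref.io import GenotypeTable
from popref.synthetic import InsertionPlan, SimConfig


@pytest.fixture
def small_config():
    return SimConfig(
        seed=7,
        n_samples=40,
        n_sites=120,
        contig_lengths={"chr1": 120_000},
        ld_block_length=20_000,
        n_founders=4,
    )


@pytest.fixture
def small_cohort(small_config):
    from popref.synthetic import simulate_cohort

    return simulate_cohort(small_config)


def make_table(dosages, contig="chr1", start_pos=100, spacing=100):
    """Genotype table from a (n_sites x n_samples) dosage list."""
    dosages = np.asarray(dosages, dtype=np.int16)
    n_sites, n_samples = dosages.shape
    sites = pd.DataFrame(
        {
            "contig": [contig] * n_sites,
            "pos": [start_pos + i * spacing for i in range(n_sites)],
            "ref": ["A"] * n_sites,
            "alt": ["C"] * n_sites,
            "rsid": [None] * n_sites,
        }
    )
    return GenotypeTable(
        sites=sites,
        samples=[f"S{i}" for i in range(n_samples)],
        dosages=dosages,
    )
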