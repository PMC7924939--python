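import numpy as np
import pytest

from carrierphylo.io_formats import Alignment, SeqRecord
from carrierphylo.simulate import SimConfig, sim_gene_family, sim_sequences, simulate_dataset


@pytest.fixture(scope="session")
def sim_truth():
    """One full default-condition simulated dataset shared across tests."""
    return simulate_dataset(SimConfig(seed=5))


@pytest.fixture(scope="session")
def small_truth():
    """A small, fast family (6 taxa, short sequences) for heavier stages."""
    cfg = SimConfig(seed=9, n_taxa=6, seq_length=120, decoys_per_taxon=8,
                    n_other_families=2)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_alignment(rows: dict[str, str]) -> Alignment:
    return Alignment([SeqRecord(k, v) for k, v in rows.items()])
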