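"""Shared fixtures: one small simulated dataset reused across module tests."""

import numpy as np
import pytest

from mtlineage.consensus import call_consensus_all, call_variants
from mtlineage.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_clones=8, cells_per_clone=25, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """200-cell simulated dataset: truth, reads and state labels."""
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_called(small_dataset):
    """Consensus-called, filtered variant matrix of the small dataset."""
    truth, reads, _states = small_dataset
    molecules = call_consensus_all(reads)
    vcm, variants = call_variants(molecules, truth.reference)
    return molecules, vcm, variants


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
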