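import numpy as np
import pytest

from netpharm.datamodel import DTIRecord, FingerprintTable
from netpharm.network import assemble_network
from netpharm.synthetic import SyntheticConfig, generate


@pytest.fixture
def tiny_fingerprints() -> FingerprintTable:
    # two drugs sharing bit b3
    return FingerprintTable(
        ["d1", "d2"],
        ["b1", "b2", "b3"],
        np.array([[1, 0, 1], [0, 1, 1]]),
    )


@pytest.fixture
def tiny_dtis() -> list[DTIRecord]:
    return [DTIRecord("d1", "T1")]


@pytest.fixture(scope="session")
def default_dataset():
    """The default planted synthetic dataset, seed 1 (shared, read-only)."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_network(default_dataset):
    return assemble_network(default_dataset.dtis)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A scaled-down config for end-to-end runs where size is irrelevant."""
    return SyntheticConfig(
        n_herbs=3,
        n_compounds=90,
        compounds_per_herb=30,
        n_targets=60,
        n_bits=120,
        n_scaffold_classes=8,
        signature_bits_per_class=10,
        n_disease_genes=10,
        n_planted=5,
        seed=7,
    )
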