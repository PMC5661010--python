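import numpy as np
import pytest

from nmrfingerprint import SyntheticConfig, generate_bucket_table, pqn_normalize
from nmrfingerprint.data_model import derive_group_labels


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared across tests."""
    return generate_bucket_table(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def normalized_dataset(default_dataset):
    table, metadata, truth = default_dataset
    return pqn_normalize(table).table, metadata, truth


@pytest.fixture(scope="session")
def combined_labels(default_dataset):
    _, metadata, _ = default_dataset
    return derive_group_labels(metadata, "combined")


@pytest.fixture(scope="session")
def conformation_labels(default_dataset):
    _, metadata, _ = default_dataset
    return derive_group_labels(metadata, "conformation")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


from nmrfingerprint.synthetic import generate_latent_class_table


def three_component_dataset(rng, **kwargs):
    """Four groups spanning exactly 3 latent components (shared by DAPC and
    acceptance tests)."""
    return generate_latent_class_table(rng, **kwargs)
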