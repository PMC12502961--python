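import numpy as np
import pytest

from ringprop import (
    FeatureScheme,
    GeneratorConfig,
    HuckelParams,
    featurize_records,
    generate_molecules,
    label_records,
)


@pytest.fixture(scope="session")
def scheme():
    return FeatureScheme()


@pytest.fixture(scope="session")
def small_records():
    """A reusable pool of 120 generated molecules."""
    return generate_molecules(GeneratorConfig(n_molecules=120, seed=1234))


@pytest.fixture(scope="session")
def small_graphs(small_records, scheme):
    return featurize_records(small_records, scheme)


@pytest.fixture(scope="session")
def small_labels(small_records):
    """Noise-free oracle labels for the small pool (read-only: shared)."""
    labels = label_records(small_records, HuckelParams(noise_sd=0.0), seed=7)
    labels.flags.writeable = False
    return labels


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
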