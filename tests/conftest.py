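import numpy as np
import pytest

from atpresi.chains import fragments_of
from atpresi.simulate import GeneratorConfig, generate_dataset, generate_worked_micro


@pytest.fixture(scope="session")
def micro_chains():
    """Three tiny hand-checkable chains."""
    return generate_worked_micro()


@pytest.fixture(scope="session")
def small_dataset():
    """20 synthetic chains with planted signal, shared across tests."""
    return generate_dataset(GeneratorConfig(n_chains=20, length_range=(51, 70), seed=42))


@pytest.fixture(scope="session")
def small_fragments(small_dataset):
    return fragments_of(small_dataset, L=17)


@pytest.fixture(scope="session")
def small_labels(small_fragments):
    return np.array([f.label for f in small_fragments])
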