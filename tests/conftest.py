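import numpy as np
import pytest

from hgstrat import by32_config, by15_config, default_tableau, generate_dataset


@pytest.fixture(scope="session")
def tableau():
    return default_tableau()


@pytest.fixture(scope="session")
def by32_dataset():
    return generate_dataset(by32_config(seed=7))


@pytest.fixture(scope="session")
def by15_dataset():
    return generate_dataset(by15_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
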