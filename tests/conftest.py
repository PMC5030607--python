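import numpy as np
import pytest
from hypothesis import settings

import gestnet as g

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dataset12() -> g.SyntheticDataset:
    """A default synthetic community of 12 with variable sampling effort."""
    return g.simulate_dataset(n=12, seed=11)


@pytest.fixture(scope="session")
def proximity12(dataset12) -> g.DyadicMatrix:
    return g.proximity_duration_matrix(dataset12.scans, dataset12.labels)


def random_matrix(n: int, seed: int, **kwargs) -> g.DyadicMatrix:
    rng = np.random.default_rng(seed)
    labels = tuple(f"i{k}" for k in range(n))
    return g.DyadicMatrix(labels=labels, values=rng.random((n, n)), **kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
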