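import numpy as np
import pytest

from cocreg import CompositionTable, Scenario, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset():
    """A modest (p=6, q=4, n=60) dense-signal dataset with strong signal."""
    sc = Scenario(p=6, q=4, n=60, predictor_design="homogeneous",
                  signal="dense", concentration=50.0, seed=5)
    return simulate_dataset(sc)


@pytest.fixture
def tiny_tables(rng):
    x = CompositionTable(rng.dirichlet(np.ones(5), size=20))
    y = CompositionTable(rng.dirichlet(np.ones(3), size=20))
    return x, y
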