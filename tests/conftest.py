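import numpy as np
import pytest

from ecoloc import BipartiteNetwork, GeneratorSpec, ParamConfig, powerlaw_bipartite


@pytest.fixture
def tiny_net():
    """2 animals x 2 plants, 3 links."""
    return BipartiteNetwork(np.array([[1, 1], [1, 0]]))


@pytest.fixture
def hetero_net():
    """Star-plus-path topology with clearly unequal degrees."""
    inc = np.array(
        [
            [1, 1, 1, 1],
            [1, 0, 0, 0],
            [1, 0, 0, 0],
            [0, 1, 0, 0],
            [0, 0, 1, 1],
        ]
    )
    return BipartiteNetwork(inc)


@pytest.fixture(scope="session")
def powerlaw_net():
    """Mid-size heterogeneous network shared across expensive tests."""
    return powerlaw_bipartite(
        GeneratorSpec(A=60, P=40, family="powerlaw", exponent=1.5, seed=0)
    )


@pytest.fixture
def default_cfg():
    return ParamConfig(delta=0.5, seed=42)
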