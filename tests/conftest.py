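import networkx as nx
import numpy as np
import pytest

from netreveal import MultifractalMeasure


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_measure():
    """k=1 measure with all base probabilities 0.5."""
    return MultifractalMeasure(m=2, k=1, P=np.full((2, 2), 0.5))


@pytest.fixture
def tiny_measure():
    """Small asymmetric-category measure used across sampler tests."""
    return MultifractalMeasure(
        m=2, k=1, P=np.array([[0.8, 0.3], [0.3, 0.7]]), L=np.array([0.5, 0.5])
    )


@pytest.fixture
def triangle():
    return nx.Graph([(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path4():
    return nx.path_graph(4)
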