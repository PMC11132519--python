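import pytest

from toh_feedback import FeatureMap, build_graph
from toh_feedback.softq import graph_arrays


@pytest.fixture(scope="session")
def graph3():
    return build_graph(3)


@pytest.fixture(scope="session")
def graph4():
    return build_graph(4)


@pytest.fixture(scope="session")
def graph5():
    return build_graph(5)


@pytest.fixture(scope="session")
def arrays4(graph4):
    return graph_arrays(graph4)


@pytest.fixture(scope="session")
def sparse8(graph4):
    return FeatureMap.sparse(graph4)
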