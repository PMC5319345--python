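import networkx as nx
import pytest

from hetdeg import extremal


@pytest.fixture
def path3() -> nx.Graph:
    return nx.path_graph(3)


@pytest.fixture
def star50() -> nx.Graph:
    return extremal.star_graph(50)


@pytest.fixture(scope="session")
def extremal_family() -> dict[int, nx.Graph]:
    """Completely heterogeneous graphs for every n in 4..500 (built once)."""
    return {n: extremal.complete_heterogeneous_graph(n) for n in range(4, 501)}
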