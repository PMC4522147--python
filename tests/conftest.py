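import networkx as nx
import pytest


def build_net(edges):
    """Weighted undirected network from {(u,v): w} or [(u,v,w)]."""
    g = nx.Graph()
    if isinstance(edges, dict):
        edges = [(u, v, w) for (u, v), w in edges.items()]
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w))
    return g


@pytest.fixture
def net_factory():
    return build_net
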