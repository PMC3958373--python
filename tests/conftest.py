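import numpy as np
import pytest

from rfcluster import Network, similarity_matrix


@pytest.fixture
def path_graph():
    """a - b - c."""
    return Network.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def chain_relation():
    """Reflexive 3-node relation with R(a,b)=0.8, R(b,c)=0.6, R(a,c)=0."""
    from rfcluster import FuzzyRelation

    g = np.array([[1.0, 0.8, 0.0], [0.8, 1.0, 0.6], [0.0, 0.6, 1.0]])
    return FuzzyRelation(g, ("a", "b", "c"))


def make_clique(net: Network, names) -> None:
    names = list(names)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            net.add_edge(names[i], names[j])


@pytest.fixture
def two_cliques_bridged():
    """Two 4-cliques joined by a single edge."""
    net = Network()
    c1 = ["a1", "a2", "a3", "a4"]
    c2 = ["b1", "b2", "b3", "b4"]
    make_clique(net, c1)
    make_clique(net, c2)
    net.add_edge("a1", "b1")
    return net, c1, c2


def random_network(n: int, p: float, rng: np.random.Generator) -> Network:
    """Erdős–Rényi network over n named nodes (may be disconnected)."""
    net = Network()
    names = [f"n{i}" for i in range(n)]
    for v in names:
        net.add_node(v)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(names[i], names[j])
    return net


def random_relation(n: int, rng: np.random.Generator):
    """A random reflexive symmetric fuzzy relation (not transitive)."""
    from rfcluster import FuzzyRelation

    g = rng.random((n, n))
    g = np.minimum(g, g.T)
    g[rng.random((n, n)) < 0.5] = 0.0
    g = np.minimum(g, g.T)
    np.fill_diagonal(g, 1.0)
    return FuzzyRelation(g, tuple(f"n{i}" for i in range(n)))


@pytest.fixture
def similarity_of():
    def _build(net: Network, **kw):
        return similarity_matrix(net, **kw)

    return _build
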