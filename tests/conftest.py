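import networkx as nx
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def path4() -> nx.Graph:
    """Path a-b-c-d."""
    return nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def star3() -> nx.Graph:
    """3-star: center c0 with leaves a, b, c."""
    return nx.Graph([("c0", "a"), ("c0", "b"), ("c0", "c")])


@pytest.fixture
def two_clique_bridge() -> nx.Graph:
    """Two 4-cliques {a,b,c,d} and {e,f,g,h} joined by the bridge d-e."""
    g = nx.Graph()
    for block in ("abcd", "efgh"):
        g.add_edges_from(
            (block[i], block[j])
            for i in range(4)
            for j in range(i + 1, 4)
        )
    g.add_edge("d", "e")
    return g


@pytest.fixture(scope="session")
def karate():
    from cesnet.datasets import karate_graph

    return karate_graph()


@pytest.fixture(scope="session")
def karate_ref():
    from cesnet.datasets import karate_reference

    return karate_reference()


def random_graphs(count: int, seed: int, n_range=(5, 30), p_range=(0.1, 0.5)):
    """Deterministic stream of connected-ish random graphs with >=1 edge."""
    import random

    rng = random.Random(seed)
    out = []
    while len(out) < count:
        n = rng.randint(*n_range)
        p = rng.uniform(*p_range)
        g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
        if g.number_of_edges() == 0:
            continue
        out.append(nx.relabel_nodes(g, {v: f"v{v:02d}" for v in g.nodes}))
    return out
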