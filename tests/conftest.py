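import numpy as np
import pytest

from colocnet.core import GeneNetwork, SeedGeneSet


@pytest.fixture
def triangle() -> GeneNetwork:
    return GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3() -> GeneNetwork:
    return GeneNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def seed_a() -> SeedGeneSet:
    return SeedGeneSet(name="a", source="common", genes=frozenset({"A"}))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_network(rng: np.random.Generator, n: int, kind: str = "gnp") -> GeneNetwork:
    """Small random connected-ish test graphs of mixed topology."""
    import networkx as nx

    seed = int(rng.integers(2**31 - 1))
    if kind == "gnp":
        g = nx.gnp_random_graph(n, min(0.9, 4.0 / n), seed=seed)
    elif kind == "ba":
        g = nx.barabasi_albert_graph(n, min(3, n - 1), seed=seed)
    elif kind == "plc":
        g = nx.powerlaw_cluster_graph(n, min(3, n - 1), 0.3, seed=seed)
    else:
        raise ValueError(kind)
    edges = [(f"N{u}", f"N{v}") for u, v in g.edges]
    nodes = [f"N{u}" for u in g.nodes]
    return GeneNetwork.from_edges(edges, extra_nodes=nodes)
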