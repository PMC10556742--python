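import numpy as np
import pytest

from comorbnet.graph import HeterogeneousGraph, NodeType, build_graph
from comorbnet.synthetic import SyntheticSpec, generate


@pytest.fixture
def toy_graph() -> HeterogeneousGraph:
    """Two overlapping disease communities, every layer populated.

    d1, d2 share gene g1; g1-g2 interact; g1 and g2 have mouse orthologs
    m1, m2 attached to a shared phenotype p1; d3 hangs off g3, whose
    ortholog m3 also shows p1.
    """
    return build_graph(
        dg=[("d1", "g1"), ("d2", "g1"), ("d2", "g2"), ("d3", "g3")],
        gg=[("g1", "g2")],
        gm=[("g1", "m1"), ("g2", "m2"), ("g3", "m3")],
        mp=[("m1", "p1"), ("m2", "p1"), ("m3", "p1")])


@pytest.fixture(scope="session")
def default_dataset():
    return generate(SyntheticSpec(), seed=7)


@pytest.fixture(scope="session")
def default_graph(default_dataset):
    return default_dataset.to_graph()


def random_typed_graph(rng: np.random.Generator, max_nodes: int = 20,
                       edge_prob: float = 0.3) -> HeterogeneousGraph:
    """A random small graph with all four typed layers."""
    counts = {t: int(rng.integers(1, max(2, max_nodes // 4)))
              for t in NodeType}
    names = {t: [f"{t.value[0].lower()}{i}" for i in range(counts[t])]
             for t in NodeType}
    g = HeterogeneousGraph()
    for t, ns in names.items():
        for n in ns:
            g.add_node(n, t)
    from comorbnet.graph import EDGE_ENDPOINTS
    for et, (ta, tb) in EDGE_ENDPOINTS.items():
        for a in names[ta]:
            for b in names[tb]:
                if a >= b and ta is tb:
                    continue
                if a != b and rng.random() < edge_prob:
                    g.add_edge(a, b, et)
    g.finalize()
    return g
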