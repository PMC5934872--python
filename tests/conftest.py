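import pytest

from mlsr import Coloring, Genome, Multigraph, instance_from_eulerian_graph
from mlsr.genome import adjacency as adj


@pytest.fixture
def example1():
    """The worked single-chromosome example: A B -C versus A -B -C.

    In pair-coded form A = {{1,2},{3,4},{5},{6}}, B = {{1,4},{3,2},{5},{6}}
    with col({1,2})=y, col({3,4})=z, col({5})=t, col({6})=x.
    """
    a = Genome([adj(1, 2), adj(3, 4), adj(5), adj(6)])
    b = Genome([adj(1, 4), adj(3, 2), adj(5), adj(6)])
    col = Coloring({adj(1, 2): "y", adj(3, 4): "z", adj(5): "t", adj(6): "x"})
    return a, b, col


@pytest.fixture
def triangle_graph():
    g = Multigraph()
    g.add_edge("u1", "u2")
    g.add_edge("u2", "u3")
    g.add_edge("u3", "u1")
    return g


@pytest.fixture
def triangle_instance(triangle_graph):
    """Six-extremity instance whose junction graph is a triangle: the tight
    witness for the 3/2-approximation (exact cost 2, greedy cost 3)."""
    return instance_from_eulerian_graph(triangle_graph)
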