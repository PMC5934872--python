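"""Adjacency and junction graphs, 2-break rewrites, Eulerian predicates.

The adjacency graph of two genomes A and B is a bipartite multigraph on
A ∪ B with ``|p ∩ q|`` edges between adjacencies p of A and q of B; its
components are paths and cycles.  The junction graph contracts the A side
to colors: its vertices are the palette and it has one edge per internal
adjacency of B joining the colors of that adjacency's two A-neighbors.
Sorting the junction graph into an all-loop (*terminal*) state by 2-breaks
is the graph shadow of a minimum-cost DCJ scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import networkx as nx

from .genome import Coloring, Genome, GenomeError

__all__ = [
    "Multigraph",
    "TwoBreak",
    "AdjacencyGraphView",
    "build_adjacency_graph",
    "build_junction_graph",
    "component_coloring",
    "apply_two_break",
    "is_eulerian",
    "is_terminal",
    "eulerian_extension",
]


class GraphError(ValueError):
    pass


@dataclass
class Multigraph:
    """Undirected multigraph with persistent edge ids; loops allowed.

    Edge ids make parallel edges distinguishable, which cycle packings and
    2-break scenarios need.  A loop contributes 2 to its vertex's degree.
    """

    vertices: set = field(default_factory=set)
    edges: dict = field(default_factory=dict)  # id -> (u, v)

    def add_vertex(self, v: Hashable) -> None:
        self.vertices.add(v)

    def add_edge(self, u: Hashable, v: Hashable, eid: Hashable | None = None) -> Hashable:
        if eid is None:
            eid = self._fresh_id()
        if eid in self.edges:
            raise GraphError(f"duplicate edge id {eid!r}")
        self.vertices.add(u)
        self.vertices.add(v)
        self.edges[eid] = (u, v)
        return eid

    def _fresh_id(self) -> int:
        n = len(self.edges)
        while n in self.edges:
            n += 1
        return n

    def endpoints(self, eid: Hashable):
        return self.edges[eid]

    def degree(self, v: Hashable) -> int:
        d = 0
        for u, w in self.edges.values():
            if u == v:
                d += 1
            if w == v:
                d += 1
        return d

    def degrees(self) -> dict:
        d = {v: 0 for v in self.vertices}
        for u, w in self.edges.values():
            d[u] += 1
            d[w] += 1
        return d

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def loops(self) -> list:
        return [eid for eid, (u, v) in self.edges.items() if u == v]

    def is_loop(self, eid: Hashable) -> bool:
        u, v = self.edges[eid]
        return u == v

    def copy(self) -> "Multigraph":
        return Multigraph(set(self.vertices), dict(self.edges))

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.vertices)
        for eid, (u, v) in self.edges.items():
            g.add_edge(u, v, key=eid)
        return g

    @classmethod
    def from_networkx(cls, g: nx.MultiGraph) -> "Multigraph":
        mg = cls(set(g.nodes))
        for u, v, key in g.edges(keys=True):
            mg.add_edge(u, v, key)
        return mg

    def edge_multiset(self) -> tuple:
        """Canonical form ignoring edge ids (sorted endpoint pairs)."""
        return tuple(sorted(tuple(sorted((u, v), key=repr)) for u, v in self.edges.values()))

    def connected(self, ignore_isolated: bool = True) -> bool:
        g = self.to_networkx()
        if ignore_isolated:
            g.remove_nodes_from([v for v in g.nodes if g.degree(v) == 0])
        if g.number_of_nodes() == 0:
            return True
        return nx.is_connected(g)


@dataclass(frozen=True)
class TwoBreak:
    """Replace two edges by a re-matching of their four endpoints.

    ``produced`` is aligned with ``consumed``: ``produced[i]`` is the new
    endpoint pair for edge id ``consumed[i]``.
    """

    consumed: tuple  # (eid1, eid2)
    produced: tuple  # ((u1, v1), (u2, v2))


def apply_two_break(g: Multigraph, tb: TwoBreak) -> Multigraph:
    """Apply a 2-break, preserving edge count and all vertex degrees."""
    e1, e2 = tb.consumed
    if e1 == e2:
        raise GraphError("a 2-break consumes two distinct edges")
    for e in (e1, e2):
        if e not in g.edges:
            raise GraphError(f"edge {e!r} not in graph")
    old = sorted(list(g.edges[e1]) + list(g.edges[e2]), key=repr)
    new = sorted([x for p in tb.produced for x in p], key=repr)
    if old != new:
        raise GraphError(f"invalid re-matching: endpoints {old} -> {new}")
    out = g.copy()
    out.edges[e1] = tuple(tb.produced[0])
    out.edges[e2] = tuple(tb.produced[1])
    return out


def is_eulerian(g: Multigraph) -> bool:
    """True iff every vertex has even degree (connectivity not required)."""
    return all(d % 2 == 0 for d in g.degrees().values())


def is_terminal(g: Multigraph) -> bool:
    """True iff every edge is a self-loop."""
    return all(u == v for u, v in g.edges.values())


def eulerian_extension(g: Multigraph, uncovered: Iterable[Hashable]) -> tuple:
    """Duplicate each edge in ``uncovered``; returns ``(g', dup_of)`` where
    ``dup_of`` maps each uncovered edge id to its artificial duplicate's id.

    When ``uncovered`` is the set of edges missed by a cycle packing whose
    cycles cover an even-degree subgraph, the result is Eulerian.
    """
    out = g.copy()
    dup_of = {}
    for eid in sorted(uncovered, key=repr):
        u, v = g.edges[eid]
        dup_of[eid] = out.add_edge(u, v, ("dup", eid))
    return out, dup_of


# ---------------------------------------------------------------------------
# Adjacency graph
# ---------------------------------------------------------------------------


@dataclass
class AdjacencyGraphView:
    """The adjacency graph AG(A, B) with its path/cycle decomposition.

    Vertices are ``("A", adj)`` / ``("B", adj)``; there is one edge per
    shared extremity, so p and q are joined by exactly ``|p ∩ q|`` edges.
    """

    a: Genome
    b: Genome
    graph: Multigraph

    def components(self) -> list:
        """Connected components as dicts with vertices, edges and a cycle flag.

        Path components are reported with their vertices in path order
        (endpoints first and last); endpoints are the external adjacencies.
        """
        g = self.graph.to_networkx()
        out = []
        for comp in sorted(nx.connected_components(g), key=lambda c: sorted(map(repr, c))):
            sub = g.subgraph(comp)
            is_cycle = all(d == 2 for _, d in sub.degree())
            verts = list(comp)
            if not is_cycle:
                ends = sorted((v for v, d in sub.degree() if d == 1), key=repr)
                order = [ends[0]]
                prev = None
                while True:
                    nbrs = [w for w in sub.neighbors(order[-1]) if w != prev]
                    if not nbrs:
                        break
                    prev = order[-1]
                    order.append(nbrs[0])
                verts = order
            out.append(
                {
                    "vertices": verts,
                    "edges": [k for _, _, k in sub.edges(keys=True)],
                    "is_cycle": is_cycle,
                }
            )
        return out


def build_adjacency_graph(a: Genome, b: Genome) -> AdjacencyGraphView:
    if a.extremities != b.extremities:
        raise GenomeError("genomes are over different extremity universes")
    a_of = a.index()
    b_of = b.index()
    g = Multigraph()
    for adj in a.adjacencies:
        g.add_vertex(("A", adj))
    for adj in b.adjacencies:
        g.add_vertex(("B", adj))
    for x in sorted(a.extremities):
        g.add_edge(("A", a_of[x]), ("B", b_of[x]), x)  # edge id = shared extremity
    return AdjacencyGraphView(a, b, g)


def component_coloring(a: Genome, b: Genome) -> Coloring:
    """Color A's adjacencies by their adjacency-graph component index.

    Every component of AG(A, B) becomes monochromatic, so the junction
    graph is terminal and the MLS cost of the resulting coloring is 0.
    """
    ag = build_adjacency_graph(a, b)
    assignment = {}
    for idx, comp in enumerate(ag.components()):
        for side, adj in comp["vertices"]:
            if side == "A":
                assignment[adj] = idx
    return Coloring(assignment)


def build_junction_graph(a: Genome, b: Genome, col: Coloring) -> Multigraph:
    """Junction graph J(A, B, col): vertices are the palette, one edge per
    internal adjacency of B joining the colors of its two A-neighbors.

    Edge ids are the internal adjacencies of B themselves, and the endpoint
    order follows the sorted extremities of that adjacency, so graph edges
    can be traced back to genome structure.
    """
    if a.extremities != b.extremities:
        raise GenomeError("genomes are over different extremity universes")
    col.validate_total(a)
    a_of = a.index()
    g = Multigraph(set(col.palette))
    for adj in sorted((x for x in b.adjacencies if len(x) == 2), key=lambda s: sorted(s)):
        p, q = sorted(adj)
        g.add_edge(col.of(a_of[p]), col.of(a_of[q]), adj)
    return g
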