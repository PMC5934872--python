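"""Maximum edge-disjoint cycle packing (MECP) on multigraphs.

The number of non-local moves in a minimum local scenario is
``e(J) - c(J)`` for the junction graph J, so computing the packing number
c(J) is the computational heart of the problem (it is NP-hard in general).

The exact solver first strips loops and parallel-edge digons — some maximum
packing always contains all loops and a maximum set of digons, by a simple
exchange argument — then enumerates the simple cycles of the remaining
simple graph and solves maximum set packing on their edge sets by exact
branch and bound.  A brute-force oracle over all edge subsets validates it
on small graphs, and the loop/digon greedy supports the 3/2-approximation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Hashable, Iterable

import networkx as nx

from .graphs import Multigraph

__all__ = [
    "Cycle",
    "CyclePacking",
    "PackingStats",
    "PackingConfig",
    "BudgetExceededError",
    "reduce_loops_digons",
    "mecp_exact",
    "mecp_bruteforce",
    "greedy_loops_digons_packing",
]


class BudgetExceededError(RuntimeError):
    """Simple-cycle enumeration exceeded the configured budget."""

    def __init__(self, reached: int, budget: int):
        super().__init__(
            f"simple-cycle enumeration budget exceeded: {reached} cycles "
            f"found, budget {budget}; raise PackingConfig.max_cycles to proceed"
        )
        self.reached = reached
        self.budget = budget


@dataclass(frozen=True)
class Cycle:
    """A cycle as aligned edge-id and vertex-walk tuples.

    ``edges[i]`` joins ``walk[i]`` and ``walk[(i+1) % l]``; a loop has a
    one-vertex walk, a digon a two-vertex walk.
    """

    edges: tuple
    walk: tuple

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class PackingStats:
    size: int
    n_loops: int
    n_digons: int
    n_longer: int


@dataclass(frozen=True)
class CyclePacking:
    """A set of pairwise edge-disjoint cycles of a host multigraph."""

    host: Multigraph
    cycles: tuple

    def __post_init__(self):
        seen: set = set()
        for cyc in self.cycles:
            for eid in cyc.edges:
                if eid not in self.host.edges:
                    raise ValueError(f"cycle edge {eid!r} not in host graph")
                if eid in seen:
                    raise ValueError(f"edge {eid!r} used by two cycles")
                seen.add(eid)

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def covered_edges(self) -> frozenset:
        return frozenset(e for c in self.cycles for e in c.edges)

    @property
    def uncovered_edges(self) -> frozenset:
        return frozenset(self.host.edges) - self.covered_edges

    def stats(self) -> PackingStats:
        n1 = sum(1 for c in self.cycles if len(c) == 1)
        n2 = sum(1 for c in self.cycles if len(c) == 2)
        return PackingStats(len(self.cycles), n1, n2, len(self.cycles) - n1 - n2)


@dataclass(frozen=True)
class PackingConfig:
    max_cycles: int = 10**6  # cap on enumerated simple cycles; exceeding errors out
    bruteforce_max_edges: int = 10


def _loop_and_digon_cycles(g: Multigraph):
    """All loops as 1-cycles plus floor(m/2) digons per parallel class."""
    loops = [Cycle((eid,), (g.edges[eid][0],)) for eid in sorted(g.loops(), key=repr)]
    by_pair = defaultdict(list)
    for eid, (u, v) in g.edges.items():
        if u != v:
            by_pair[frozenset((u, v))].append(eid)
    digons = []
    for pair in sorted(by_pair, key=lambda p: sorted(map(repr, p))):
        eids = sorted(by_pair[pair], key=repr)
        u, v = sorted(pair, key=repr)
        for i in range(len(eids) // 2):
            digons.append(Cycle((eids[2 * i], eids[2 * i + 1]), (u, v)))
    return loops, digons


def reduce_loops_digons(g: Multigraph):
    """Remove all loops and a maximum digon set, leaving a simple graph.

    Returns ``(reduced, c1, c2, removed)`` with ``removed`` the list of
    packed :class:`Cycle` objects.  Some MECP of ``g`` consists of exactly
    these cycles plus an MECP of the reduced graph.
    """
    loops, digons = _loop_and_digon_cycles(g)
    removed = loops + digons
    used = {e for c in removed for e in c.edges}
    reduced = Multigraph(set(g.vertices), {e: uv for e, uv in g.edges.items() if e not in used})
    return reduced, len(loops), len(digons), removed


def _simple_cycles_of_simple_graph(g: Multigraph, max_cycles: int):
    """Simple cycles (length >= 3) of a loop-free simple graph, as Cycles."""
    nxg = nx.Graph()
    nxg.add_nodes_from(g.vertices)
    eid_of = {}
    for eid, (u, v) in g.edges.items():
        nxg.add_edge(u, v)
        eid_of[frozenset((u, v))] = eid
    cycles = []
    for walk in nx.simple_cycles(nxg):
        if len(cycles) >= max_cycles:
            raise BudgetExceededError(len(cycles) + 1, max_cycles)
        # canonical rotation: start at smallest vertex, smaller neighbor next
        i = min(range(len(walk)), key=lambda j: repr(walk[j]))
        walk = walk[i:] + walk[:i]
        if len(walk) > 2 and repr(walk[-1]) < repr(walk[1]):
            walk = [walk[0]] + walk[1:][::-1]
        edges = tuple(
            eid_of[frozenset((walk[i], walk[(i + 1) % len(walk)]))] for i in range(len(walk))
        )
        cycles.append(Cycle(edges, tuple(walk)))
    cycles.sort(key=lambda c: (len(c), sorted(map(repr, c.edges))))
    return cycles


def _max_set_packing(cycles, n_edges: int):
    """Exact maximum edge-disjoint selection by depth-first branch and bound.

    Cycles are tried in their given order, include-first, so among optima the
    first (lexicographically smallest index set) found is returned.
    """
    edge_ids = sorted({e for c in cycles for e in c.edges}, key=repr)
    bit = {e: 1 << i for i, e in enumerate(edge_ids)}
    masks = [sum(bit[e] for e in c.edges) for c in cycles]
    n = len(cycles)
    best: list = []
    best_size = -1

    def rec(i: int, used: int, chosen: list):
        nonlocal best, best_size
        if len(chosen) + (n - i) <= best_size:
            return
        if i == n:
            if len(chosen) > best_size:
                best_size = len(chosen)
                best = list(chosen)
            return
        if not masks[i] & used:
            chosen.append(i)
            rec(i + 1, used | masks[i], chosen)
            chosen.pop()
        rec(i + 1, used, chosen)

    rec(0, 0, [])
    return [cycles[i] for i in best]


def mecp_exact(g: Multigraph, config: PackingConfig | None = None) -> CyclePacking:
    """A maximum edge-disjoint cycle packing, deterministic under fixed config.

    Raises :class:`BudgetExceededError` if the reduced graph has more simple
    cycles than ``config.max_cycles``.
    """
    config = config or PackingConfig()
    reduced, _c1, _c2, removed = reduce_loops_digons(g)
    candidates = _simple_cycles_of_simple_graph(reduced, config.max_cycles)
    packed = _max_set_packing(candidates, reduced.n_edges)
    return CyclePacking(g, tuple(removed) + tuple(packed))


def _all_cycles_bruteforce(g: Multigraph):
    """Every simple cycle of a small multigraph, via edge-subset exhaustion.

    A nonempty edge subset is a cycle iff it is connected and 2-regular on
    its support (a loop counting 2).
    """
    eids = sorted(g.edges, key=repr)
    cycles = []
    for mask in range(1, 1 << len(eids)):
        subset = [eids[i] for i in range(len(eids)) if mask >> i & 1]
        deg: dict = defaultdict(int)
        for e in subset:
            u, v = g.edges[e]
            deg[u] += 1
            deg[v] += 1
        if any(d != 2 for d in deg.values()):
            continue
        sub = nx.MultiGraph()
        for e in subset:
            u, v = g.edges[e]
            sub.add_edge(u, v, key=e)
        if not nx.is_connected(sub):
            continue
        cycles.append(_walk_cycle(g, subset))
    return cycles


def _walk_cycle(g: Multigraph, subset) -> Cycle:
    """Trace a connected 2-regular edge set into an aligned Cycle."""
    if len(subset) == 1:
        (e,) = subset
        u, v = g.edges[e]
        if u == v:
            return Cycle((e,), (u,))
        raise ValueError("single non-loop edge is not a cycle")
    incident = defaultdict(list)
    for e in subset:
        u, v = g.edges[e]
        incident[u].append(e)
        if u != v:
            incident[v].append(e)
    start = sorted(incident, key=repr)[0]
    walk = [start]
    edges = []
    used: set = set()
    cur = start
    while len(edges) < len(subset):
        e = next(x for x in sorted(incident[cur], key=repr) if x not in used)
        used.add(e)
        u, v = g.edges[e]
        nxt = v if u == cur else u
        edges.append(e)
        if len(edges) < len(subset):
            walk.append(nxt)
        cur = nxt
    if cur != start:
        raise ValueError("edge set does not close into a single cycle")
    return Cycle(tuple(edges), tuple(walk))


def mecp_bruteforce(g: Multigraph, max_edges: int = 10) -> CyclePacking:
    """Provably maximum packing by exhaustive search; oracle for small graphs."""
    if g.n_edges > max_edges:
        raise ValueError(f"brute-force bound exceeded: {g.n_edges} edges > {max_edges}")
    cycles = _all_cycles_bruteforce(g)
    cycles.sort(key=lambda c: (len(c), sorted(map(repr, c.edges))))
    packed = _max_set_packing(cycles, g.n_edges)
    return CyclePacking(g, tuple(packed))


def greedy_loops_digons_packing(g: Multigraph) -> CyclePacking:
    """The packing of all loops and floor(m/2) digons per parallel class.

    This is the cycle collection behind the 3/2-approximation: it needs no
    cycle enumeration and yields the scenario cost e - c1 - c2.
    """
    loops, digons = _loop_and_digon_cycles(g)
    return CyclePacking(g, tuple(loops) + tuple(digons))
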