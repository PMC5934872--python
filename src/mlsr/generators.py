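"""Synthetic instance generators and the exhaustive search oracle.

Random genome pairs are produced by scrambling an identity genome with
random DCJ moves; random Eulerian multigraphs are unions of random closed
walks; and any connected Eulerian multigraph can be turned into an MLS
instance whose junction graph reproduces it exactly (the construction that
proves MLS NP-hard doubles as a verified instance factory).  A uniform-cost
search over colored-DCJ states provides an independent optimum on tiny
instances.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome import (
    Adjacency,
    BlockGenome,
    Chromosome,
    Coloring,
    DcjMove,
    Genome,
    GenomeError,
    apply_move,
    block_to_adjacency,
)
from .graphs import Multigraph, build_junction_graph, is_eulerian
from .hic import HicDataset

__all__ = [
    "InstanceBundle",
    "SearchBudgetError",
    "random_genome_pair",
    "random_linear_block_genome",
    "random_eulerian_multigraph",
    "instance_from_eulerian_graph",
    "exhaustive_min_cost_search",
    "synthetic_hic",
]


class SearchBudgetError(RuntimeError):
    """The exhaustive search exceeded its cost or state budget."""


@dataclass(frozen=True)
class InstanceBundle:
    a: Genome
    b: Genome
    coloring: Coloring | None = None
    provenance: Mapping | None = None


# ---------------------------------------------------------------------------
# Random genome pairs
# ---------------------------------------------------------------------------


def _uncolored_rewrites(genome: Genome):
    """All legal DCJ rewrites of a genome, ignoring colors."""
    adjs = sorted(genome.adjacencies, key=sorted)
    rewrites = []
    for p, q in itertools.combinations(adjs, 2):
        if len(p) == 2 and len(q) == 2:
            a, b = sorted(p)
            c, d = sorted(q)
            rewrites.append((p, q, (frozenset((a, c)), frozenset((b, d)))))
            rewrites.append((p, q, (frozenset((a, d)), frozenset((b, c)))))
        elif len(p) + len(q) == 3:
            pair, tel = (p, q) if len(p) == 2 else (q, p)
            (t,) = tel
            a, b = sorted(pair)
            rewrites.append((pair, tel, (frozenset((a, t)), frozenset((b,)))))
            rewrites.append((pair, tel, (frozenset((b, t)), frozenset((a,)))))
        else:
            (t1,) = p
            (t2,) = q
            rewrites.append((p, q, (frozenset((t1, t2)),)))
    for p in adjs:
        if len(p) == 2:
            a, b = sorted(p)
            rewrites.append((p, None, (frozenset((a,)), frozenset((b,)))))
    return rewrites


def random_genome_pair(
    n_blocks: int, n_linear_chromosomes: int, n_moves: int, seed: int
) -> InstanceBundle:
    """An identity genome A and a genome B derived by random DCJ moves.

    With ``n_linear_chromosomes == 0`` the genome is one circular
    chromosome.  Deterministic under the seed; B shares A's extremity
    universe, and MLS(A, B, col) <= number of applied moves for any col.
    """
    if n_blocks < 1:
        raise ValueError("need at least one block")
    if not 0 <= n_linear_chromosomes <= n_blocks:
        raise ValueError("infeasible chromosome count")
    rng = np.random.default_rng(seed)
    names = [str(i) for i in range(1, n_blocks + 1)]
    if n_linear_chromosomes == 0:
        chromosomes = [Chromosome(tuple(names), circular=True)]
    else:
        cuts = sorted(
            rng.choice(n_blocks - 1, size=n_linear_chromosomes - 1, replace=False).tolist()
            if n_linear_chromosomes > 1
            else []
        )
        bounds = [0] + [c + 1 for c in cuts] + [n_blocks]
        chromosomes = [
            Chromosome(tuple(names[i:j])) for i, j in zip(bounds, bounds[1:])
        ]
    bg = BlockGenome(tuple(chromosomes))
    a, _names = block_to_adjacency(bg)
    adjs = set(a.adjacencies)
    for _ in range(n_moves):
        options = _uncolored_rewrites(Genome(adjs))
        p, q, produced = options[int(rng.integers(len(options)))]
        adjs.discard(p)
        if q is not None:
            adjs.discard(q)
        adjs.update(produced)
    b = Genome(adjs)
    return InstanceBundle(
        a,
        b,
        provenance={
            "generator": "random_genome_pair",
            "n_blocks": n_blocks,
            "n_linear": n_linear_chromosomes,
            "n_moves": n_moves,
            "seed": seed,
        },
    )


def random_linear_block_genome(
    n_blocks: int, n_chromosomes: int, seed: int
) -> BlockGenome:
    """A random multi-chromosomal linear genome: blocks shuffled, signed at
    random, and split into ``n_chromosomes`` nonempty chromosomes."""
    if not 1 <= n_chromosomes <= n_blocks:
        raise ValueError("infeasible chromosome count")
    rng = np.random.default_rng(seed)
    names = [str(i) for i in range(1, n_blocks + 1)]
    rng.shuffle(names)
    signs = rng.integers(2, size=n_blocks)
    tokens = [f"-{n}" if s else n for n, s in zip(names, signs)]
    cuts = sorted(
        rng.choice(n_blocks - 1, size=n_chromosomes - 1, replace=False).tolist()
        if n_chromosomes > 1
        else []
    )
    bounds = [0] + [c + 1 for c in cuts] + [n_blocks]
    return BlockGenome(
        tuple(Chromosome(tuple(tokens[i:j])) for i, j in zip(bounds, bounds[1:]))
    )


# ---------------------------------------------------------------------------
# Eulerian multigraphs and the junction-graph-realizing instances
# ---------------------------------------------------------------------------


def random_eulerian_multigraph(
    n_vertices: int, n_edges: int, seed: int, connected: bool = False
) -> Multigraph:
    """A random Eulerian multigraph built from random closed walks.

    With ``connected=True`` a single closed walk visits every vertex, which
    requires ``n_edges >= n_vertices``; otherwise the edge count is split
    over several closed walks and vertices may stay isolated.
    """
    if n_vertices < 1 or n_edges < 1:
        raise ValueError("need at least one vertex and one edge")
    if connected and n_edges < n_vertices:
        raise ValueError("a connected Eulerian graph needs n_edges >= n_vertices")
    rng = np.random.default_rng(seed)
    g = Multigraph(set(range(n_vertices)))

    def add_walk(sequence):
        for u, v in zip(sequence, sequence[1:] + sequence[:1]):
            g.add_edge(int(u), int(v))

    if connected:
        seq = list(range(n_vertices)) + rng.integers(
            n_vertices, size=n_edges - n_vertices
        ).tolist()
        rng.shuffle(seq)
        add_walk(seq)
    else:
        remaining = n_edges
        while remaining > 0:
            size = int(rng.integers(1, remaining + 1))
            seq = rng.integers(n_vertices, size=size).tolist()
            add_walk(seq)
            remaining -= size
    if not is_eulerian(g):  # pragma: no cover - construction guarantees this
        raise AssertionError("closed-walk construction must be Eulerian")
    return g


def _eulerian_tour(g: Multigraph):
    """Hierholzer's algorithm with smallest-neighbor tie-breaking."""
    incident: dict = {v: [] for v in g.vertices}
    for eid, (u, v) in g.edges.items():
        incident[u].append(eid)
        if u != v:
            incident[v].append(eid)
    for lst in incident.values():
        lst.sort(key=lambda e: (repr(sorted(map(repr, g.edges[e]))), repr(e)))
    used: set = set()
    start = sorted((v for v in g.vertices if incident[v]), key=repr)[0]
    stack = [start]
    tour = []
    while stack:
        v = stack[-1]
        nxt = next((e for e in incident[v] if e not in used), None)
        if nxt is None:
            tour.append(stack.pop())
        else:
            used.add(nxt)
            x, y = g.edges[nxt]
            stack.append(y if x == v else x)
    tour.reverse()
    return tour[:-1]  # closed walk: last vertex repeats the first


def instance_from_eulerian_graph(g: Multigraph) -> InstanceBundle:
    """An MLS instance whose junction graph equals ``g``.

    An Eulerian tour u1..un gives A = {1,2},{3,4},...,{2n-1,2n} and
    B = {2,3},{4,5},...,{2n,1}, with the i-th pair of A colored u_i; the
    construction is verified by rebuilding the junction graph.
    """
    if not g.connected():
        raise ValueError("graph must be connected")
    if not is_eulerian(g):
        raise ValueError("graph must be Eulerian")
    tour = _eulerian_tour(g)
    n = len(tour)
    if n != g.n_edges:  # pragma: no cover
        raise AssertionError("tour length must equal edge count")
    a = Genome(frozenset((2 * i - 1, 2 * i)) for i in range(1, n + 1))
    b = Genome(frozenset((2 * i, 2 * i % (2 * n) + 1)) for i in range(1, n + 1))
    col = Coloring(
        {frozenset((2 * i - 1, 2 * i)): tour[i - 1] for i in range(1, n + 1)}
    )
    j = build_junction_graph(a, b, col)
    active = {v for v in g.vertices if g.degree(v) > 0}
    if j.edge_multiset() != g.edge_multiset() or set(j.vertices) != active:
        raise AssertionError("junction graph does not reproduce the input graph")
    return InstanceBundle(
        a, b, col, provenance={"generator": "instance_from_eulerian_graph"}
    )


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------


def _raw_successors(state, palette):
    """Successor colored-genome states of one DCJ, as (state, cost) pairs.

    A state is a frozenset of (adjacency, color) pairs.  Works on raw
    tuples for speed; mirrors the four rewrite templates exactly.
    """
    items = sorted(state, key=lambda ac: sorted(ac[0]))
    out = set()

    def emit(removed, added_colored, cost):
        out.add((state.difference(removed).union(added_colored), cost))

    for (p, x), (q, y) in itertools.combinations(items, 2):
        cost = 0 if x == y else 1
        attributions = ((x, y),) if x == y else ((x, y), (y, x))
        if len(p) == 1 and len(q) == 1:
            (t1,) = p
            (t2,) = q
            joined = frozenset((t1, t2))
            for c in {x, y}:
                emit([(p, x), (q, y)], [(joined, c)], cost)
            continue
        pair, other = (p, q) if len(p) == 2 else (q, p)
        px, ox = (x, y) if len(p) == 2 else (y, x)
        cost = 0 if px == ox else 1
        attributions = ((px, ox),) if px == ox else ((px, ox), (ox, px))
        a_, b_ = sorted(pair)
        if len(other) == 2:
            c_, d_ = sorted(other)
            rematches = (
                (frozenset((a_, c_)), frozenset((b_, d_))),
                (frozenset((a_, d_)), frozenset((b_, c_))),
            )
        else:
            (t,) = other
            rematches = (
                (frozenset((a_, t)), frozenset((b_,))),
                (frozenset((b_, t)), frozenset((a_,))),
            )
        for r1, r2 in rematches:
            for c1, c2 in attributions:
                emit([(pair, px), (other, ox)], [(r1, c1), (r2, c2)], cost)
    for p, x in items:
        if len(p) != 2:
            continue
        a_, b_ = sorted(p)
        ea, eb = frozenset((a_,)), frozenset((b_,))
        for z in palette:
            cost = 0 if z == x else 1
            emit([(p, x)], [(ea, x), (eb, z)], cost)
            emit([(p, x)], [(ea, z), (eb, x)], cost)
    return out


def _exhaustive_raw(
    a: Genome,
    b: Genome,
    col: Coloring,
    cost_cap: int | None = None,
    max_states: int = 300_000,
) -> int:
    """Plain uniform-cost search over full colored-genome states.

    The reference for :func:`exhaustive_min_cost_search` on very small
    instances; exponentially slower because it walks zero-cost moves
    explicitly.
    """
    if a.extremities != b.extremities:
        raise GenomeError("genomes are over different extremity universes")
    col.validate_total(a)
    palette = tuple(sorted(col.palette, key=repr))
    target_adjs = b.adjacencies

    start = frozenset((adj, c) for adj, c in col.items())
    dist = {start: 0}
    counter = itertools.count()
    heap = [(0, next(counter), start)]
    while heap:
        cost, _, state = heapq.heappop(heap)
        if cost > dist.get(state, cost):
            continue
        if frozenset(adj for adj, _ in state) == target_adjs:
            return cost
        if cost_cap is not None and cost > cost_cap:
            raise SearchBudgetError(f"no scenario of cost <= {cost_cap} found")
        for nxt, mcost in _raw_successors(state, palette):
            nd = cost + mcost
            if nd < dist.get(nxt, nd + 1):
                dist[nxt] = nd
                heapq.heappush(heap, (nd, next(counter), nxt))
        if len(dist) > max_states:
            raise SearchBudgetError(f"state budget {max_states} exceeded")
    raise SearchBudgetError("search space exhausted without reaching B")


def exhaustive_min_cost_search(
    a: Genome,
    b: Genome,
    col: Coloring,
    cost_cap: int | None = None,
    max_states: int = 2_000_000,
) -> int:
    """True minimum non-local count by exhaustive search, independent of the
    junction-graph/cycle-packing theory.

    States connected by zero-cost moves are collapsed before searching:
    a zero-cost DCJ never moves an extremity between color classes, and
    within one class any pairing of its extremities is reachable for free
    (split every pair keeping its color, then rejoin).  A colored-genome
    state is therefore equivalent, up to free moves, to its extremity ->
    color map, and a unit-cost move either *transfers* one extremity to
    another class or *exchanges* two extremities between classes:

    * transfer of e from class x to y: legal unless y is empty and x = {e}
      (join with a member of y, or split a pair of x giving the new
      telomere color y);
    * exchange of e in x with f in y: legal unless both classes are
      singletons (cut a pair of the larger class against the other).

    B is reached exactly when the map is constant on every internal
    adjacency of B.  A* over these maps with the admissible heuristic
    ceil(violated B-pairs / 2) (one move recolors at most two extremities)
    gives the exact optimum.  Cross-validated against the unquotiented
    search (:func:`_exhaustive_raw`) in the test suite.
    """
    if a.extremities != b.extremities:
        raise GenomeError("genomes are over different extremity universes")
    col.validate_total(a)
    exts = sorted(a.extremities)
    pos = {x: i for i, x in enumerate(exts)}
    palette = sorted(col.palette, key=repr)
    cindex = {c: i for i, c in enumerate(palette)}
    k = len(palette)
    n = len(exts)
    start_list = [0] * n
    for adj, c in col.items():
        for x in adj:
            start_list[pos[x]] = cindex[c]
    start = tuple(start_list)
    bpairs = [tuple(pos[x] for x in adj) for adj in b.adjacencies if len(adj) == 2]

    def h(m) -> int:
        v = sum(1 for i, j in bpairs if m[i] != m[j])
        return (v + 1) // 2

    def successors(m):
        counts = [0] * k
        for c in m:
            counts[c] += 1
        out = []
        for i in range(n):
            x = m[i]
            for y in range(k):
                if y == x:
                    continue
                if counts[y] >= 1 or counts[x] >= 2:
                    nm = list(m)
                    nm[i] = y
                    out.append(tuple(nm))
        for i in range(n):
            for j in range(i + 1, n):
                x, y = m[i], m[j]
                if x == y or (counts[x] < 2 and counts[y] < 2):
                    continue
                nm = list(m)
                nm[i], nm[j] = y, x
                out.append(tuple(nm))
        return out

    dist = {start: 0}
    counter = itertools.count()
    heap = [(h(start), next(counter), 0, start)]
    while heap:
        f, _, g_cost, m = heapq.heappop(heap)
        if g_cost > dist.get(m, g_cost):
            continue
        if cost_cap is not None and g_cost > cost_cap:
            raise SearchBudgetError(f"no scenario of cost <= {cost_cap} found")
        if h(m) == 0:
            return g_cost
        for nm in successors(m):
            nd = g_cost + 1
            if nd < dist.get(nm, nd + 1):
                dist[nm] = nd
                heapq.heappush(heap, (nd + h(nm), next(counter), nd, nm))
        if len(dist) > max_states:
            raise SearchBudgetError(f"state budget {max_states} exceeded")
    raise SearchBudgetError("search space exhausted without reaching B")


# ---------------------------------------------------------------------------
# Synthetic Hi-C
# ---------------------------------------------------------------------------


def synthetic_hic(
    n_chroms: int,
    bins_per_chrom: int,
    planted_clusters: int,
    noise: float,
    seed: int,
    bin_size: int = 10_000,
):
    """Synthetic raw contact matrices with power-law 1D decay and elevated
    contacts inside planted 3D clusters.

    Returns ``(dataset, labels)`` with one ground-truth cluster label per
    bin.  ``noise`` scales additive symmetric uniform noise.  The decay of
    the mean contact with distance is a property of the base signal; with
    more than one planted cluster the cluster boost adds distance-independent
    structure on top of it.
    """
    if n_chroms < 1 or bins_per_chrom < 1 or planted_clusters < 1:
        raise ValueError("sizes must be positive")
    n = n_chroms * bins_per_chrom
    if planted_clusters > n:
        raise ValueError("more clusters than bins")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms) for _ in range(bins_per_chrom)]
    starts = [(i % bins_per_chrom) * bin_size for i in range(n)]
    bins = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": [s + bin_size for s in starts]}
    )
    labels = np.empty(n, dtype=int)
    labels[: planted_clusters] = np.arange(planted_clusters)  # every cluster nonempty
    labels[planted_clusters:] = rng.integers(planted_clusters, size=n - planted_clusters)
    rng.shuffle(labels)
    same_chrom = np.equal.outer(np.asarray(chroms), np.asarray(chroms))
    pos = np.arange(n) % bins_per_chrom
    d = np.abs(np.subtract.outer(pos, pos))
    base = np.where(same_chrom, 10.0 / np.sqrt(1.0 + d), 1.0)
    boost = 100.0 * np.equal.outer(labels, labels)
    eps = rng.uniform(-1.0, 1.0, size=(n, n))
    eps = noise * (eps + eps.T) / 2.0
    raw = np.clip(base + boost + eps, 0.0, None)
    raw = (raw + raw.T) / 2.0
    return HicDataset(bins, raw), labels
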