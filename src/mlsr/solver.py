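"""Minimum local scenario (MLS) solver.

The cost of a minimum local scenario transforming genome A into genome B
under a coloring of A equals ``e(J) - c(J)``, where J is the junction graph
and c(J) the size of a maximum edge-disjoint cycle packing.  This module
computes that cost, the companion lower bound

    w >= (2/3) e(J) - (1/3) c2(J) - (2/3) c1(J),

and, constructively, an explicit DCJ scenario achieving the cost:

1. pack J and duplicate the uncovered edges to get an Eulerian extension J';
2. *cap* the genomes — add artificial extremities so every adjacency becomes
   a pair — realizing J' (up to loops) as the junction graph of the capped
   instance;
3. sort each packed cycle by 2-breaks, each lifted to a single non-local DCJ
   on the capped genome, until the junction graph is terminal (all loops);
4. finish with zero-cost moves inside the now monochromatic components of
   the adjacency graph;
5. project the capped scenario back down to the original genomes.

The greedy loop/digon packing drives the same pipeline to a 3/2-approximate
scenario with no cycle enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import networkx as nx

from .genome import (
    Adjacency,
    Coloring,
    DcjMove,
    Genome,
    GenomeError,
    apply_move,
    replay,
)
from .graphs import (
    Multigraph,
    TwoBreak,
    apply_two_break,
    build_junction_graph,
    eulerian_extension,
    is_eulerian,
    is_terminal,
)
from .packing import (
    CyclePacking,
    PackingConfig,
    greedy_loops_digons_packing,
    mecp_exact,
)

__all__ = [
    "MlsResult",
    "CappedInstance",
    "MlsInternalError",
    "mls_cost",
    "min_local_scenario",
    "approx_scenario",
    "two_break_sort",
    "cap_instance",
    "mlps_gap_bound",
]


class MlsInternalError(RuntimeError):
    """A consistency check inside the scenario construction failed."""


@dataclass(frozen=True)
class MlsResult:
    """Result of an MLS computation.

    ``cost`` is ``e(J) - |packing|``: the exact optimum when the packing is
    maximum, an upper bound within factor 3/2 for the greedy packing.  When
    present, ``scenario`` replays A into B with at most ``cost`` non-local
    moves (exactly ``cost`` for the exact solver).
    """

    cost: int
    junction_edges: int
    packing: CyclePacking
    lower_bound: Fraction
    scenario: tuple | None = None

    @property
    def n_local(self) -> int | None:
        if self.scenario is None:
            return None
        return len(self.scenario) - self.n_nonlocal

    @property
    def n_nonlocal(self) -> int | None:
        if self.scenario is None:
            return None
        return sum(m.cost for m in self.scenario)


@dataclass(frozen=True)
class CappedInstance:
    """Genome extensions realizing an Eulerian extension of the junction graph.

    Every adjacency of ``a_hat``/``b_hat`` is a pair; original adjacencies
    map one-to-one into the non-telomeric pairs.  ``edge_origin`` records,
    for every internal pair of ``b_hat``, whether it realizes an original
    junction edge (``("orig", eid)``), an artificial duplicate
    (``("dup", eid)``), or only a loop (``("loop", None)``).
    """

    a_hat: Genome
    b_hat: Genome
    col_hat: Coloring
    artificial: frozenset
    telomeric_pairs: frozenset
    edge_origin: dict
    jprime: Multigraph


def _check_instance(a: Genome, b: Genome, col: Coloring) -> None:
    if a.extremities != b.extremities:
        raise GenomeError("genomes are over different extremity universes")
    col.validate_total(a)


def _lower_bound(j: Multigraph) -> Fraction:
    from .packing import _loop_and_digon_cycles

    loops, digons = _loop_and_digon_cycles(j)
    return (
        Fraction(2, 3) * j.n_edges
        - Fraction(1, 3) * len(digons)
        - Fraction(2, 3) * len(loops)
    )


def mls_cost(
    a: Genome, b: Genome, col: Coloring, config: PackingConfig | None = None
) -> MlsResult:
    """Exact MLS cost ``e(J) - c(J)`` without scenario construction."""
    _check_instance(a, b, col)
    j = build_junction_graph(a, b, col)
    packing = mecp_exact(j, config)
    return MlsResult(
        cost=j.n_edges - len(packing),
        junction_edges=j.n_edges,
        packing=packing,
        lower_bound=_lower_bound(j),
    )


def mlps_gap_bound(d_mlps: int, d_mls: int, alpha) -> Fraction:
    """Upper bound ``(d_MLPS - d_MLS) * alpha`` on the length excess delta
    of an optimal scenario under the (1, 1+alpha) local/non-local cost pair.

    ``d_mlps`` (minimum non-local count among parsimonious scenarios) is
    user-supplied; computing it is outside this package's scope.
    """
    if d_mls < 0 or d_mlps < d_mls:
        raise ValueError("require d_mlps >= d_mls >= 0")
    alpha = Fraction(alpha)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return (d_mlps - d_mls) * alpha


# ---------------------------------------------------------------------------
# 2-break sorting of a packed graph
# ---------------------------------------------------------------------------


def two_break_sort(g: Multigraph, packing: CyclePacking) -> list:
    """A 2-break sequence of length ``e(g) - |packing|`` sorting ``g`` to a
    terminal (all-loop) graph, splitting one loop off a packed cycle at a time.

    Requires the packing to cover every edge of ``g`` (always possible when
    g is Eulerian).
    """
    if packing.uncovered_edges:
        raise ValueError("packing does not cover the graph")
    breaks = []
    for cyc in sorted(packing.cycles, key=lambda c: sorted(map(repr, c.edges))):
        l = len(cyc)
        if l == 1:
            continue
        walk = cyc.walk
        anchor = walk[0]
        chain = cyc.edges[0]
        for i in range(1, l):
            v_hi = walk[(i + 1) % l]
            breaks.append(
                TwoBreak(
                    consumed=(chain, cyc.edges[i]),
                    produced=((anchor, v_hi), (walk[i], walk[i])),
                )
            )
    # sanity: the sequence really terminalizes the graph
    state = g
    for tb in breaks:
        state = apply_two_break(state, tb)
    if not is_terminal(state):
        raise MlsInternalError("2-break sort did not reach a terminal graph")
    return breaks


# ---------------------------------------------------------------------------
# Capping
# ---------------------------------------------------------------------------


def cap_instance(
    a: Genome, b: Genome, col: Coloring, packing: CyclePacking
) -> CappedInstance:
    """Extend (A, B, col) into circular-style sets of pairs whose junction
    graph agrees with the Eulerian extension J' on all non-loop edges.

    J' duplicates every junction edge missed by ``packing``.  The duplicate
    edges are realized as chains of telomeric pairs: cycles among them are
    realized as closed chains, the remaining forest as open chains; open
    chain ends and capped external adjacencies are then joined pairwise by
    matching colors, closing every adjacency-graph path into a cycle.
    """
    _check_instance(a, b, col)
    j = build_junction_graph(a, b, col)
    if set(packing.host.edges) != set(j.edges):
        raise ValueError("packing host is not the junction graph of this instance")
    uncovered = packing.uncovered_edges
    jprime, dup_of = eulerian_extension(j, uncovered)
    if not is_eulerian(jprime):
        raise MlsInternalError("Eulerian extension is not Eulerian")

    universe = a.extremities
    next_label = (max(universe) + 1) if universe else 1
    artificial: list[int] = []

    def fresh() -> int:
        nonlocal next_label
        x = next_label
        next_label += 1
        artificial.append(x)
        return x

    a_pairs: dict = {}  # adjacency -> color
    b_pairs: list = []
    edge_origin: dict = {}
    for adj in a.adjacencies:
        if len(adj) == 2:
            a_pairs[adj] = col.of(adj)
    for adj in b.adjacencies:
        if len(adj) == 2:
            b_pairs.append(adj)
            edge_origin[adj] = ("orig", adj)

    # ports awaiting closure: color -> list of extremities
    ports_need_b: dict = {}  # extremity lives in a_hat, must join a b_hat pair
    ports_need_a: dict = {}  # extremity lives in b_hat, must join an a_hat pair

    def add_port(table: dict, color, ext: int) -> None:
        table.setdefault(color, []).append(ext)

    # 1. cap the external adjacencies of A, then of B
    a_index = a.index()
    for adj in sorted((x for x in a.adjacencies if len(x) == 1), key=sorted):
        (u,) = adj
        o = fresh()
        a_pairs[frozenset((u, o))] = col.of(adj)
        add_port(ports_need_b, col.of(adj), o)
    for adj in sorted((x for x in b.adjacencies if len(x) == 1), key=sorted):
        (v,) = adj
        o = fresh()
        pair = frozenset((v, o))
        b_pairs.append(pair)
        edge_origin[pair] = ("loop", None)
        add_port(ports_need_a, col.of(a_index[v]), o)

    # 2. realize the duplicated edges (J' - J) as chains of telomeric pairs.
    #    Cycles among them (possible only for non-maximum packings) become
    #    closed chains; the remaining forest is split into open trails.
    ext_nx = nx.MultiGraph()
    ext_nx.add_nodes_from(jprime.vertices)
    for orig, dup in dup_of.items():
        u, v = jprime.edges[dup]
        ext_nx.add_edge(u, v, key=orig)  # key back-references the original edge

    def realize_chain(steps, closed: bool) -> None:
        # steps: list of (u, v, orig_eid) walked in order
        colors = [steps[0][0]] + [s[1] for s in steps]
        tel = []
        for x in colors[:-1] if closed else colors:
            t = (fresh(), fresh())
            a_pairs[frozenset(t)] = None  # color filled below
            tel.append(t)
        for idx, x in enumerate(colors[: len(tel)]):
            a_pairs[frozenset(tel[idx])] = x
        for k, (u, v, orig) in enumerate(steps):
            left = tel[k]
            right = tel[(k + 1) % len(tel)] if closed else tel[k + 1]
            pair = frozenset((left[1], right[0]))
            b_pairs.append(pair)
            edge_origin[pair] = ("dup", orig)
        if not closed:
            add_port(ports_need_b, colors[0], tel[0][0])
            add_port(ports_need_b, colors[-1], tel[-1][1])

    while True:
        try:
            cycle = nx.find_cycle(ext_nx)
        except nx.exception.NetworkXNoCycle:
            break
        realize_chain([(u, v, k) for u, v, k in cycle], closed=True)
        ext_nx.remove_edges_from(cycle)
    while ext_nx.number_of_edges():
        odd = sorted((v for v, d in ext_nx.degree() if d % 2 == 1), key=repr)
        if not odd:  # pragma: no cover - forest always has leaves
            raise MlsInternalError("forest of duplicate edges has no odd vertex")
        cur = odd[0]
        steps = []
        while ext_nx.degree(cur) > 0:
            nxt = sorted(ext_nx[cur], key=repr)[0]
            key = sorted(ext_nx[cur][nxt], key=repr)[0]
            steps.append((cur, nxt, key))
            ext_nx.remove_edge(cur, nxt, key)
            cur = nxt
        realize_chain(steps, closed=False)

    # 3. close the ports color by color.  Every adjacency-graph path has two
    #    ends and every junction-graph vertex has even degree in J', so the
    #    ports of each color pair up.
    for color in sorted(set(ports_need_a) | set(ports_need_b), key=repr):
        need_a = ports_need_a.get(color, [])
        need_b = ports_need_b.get(color, [])
        while len(need_a) >= 2:
            e1, e2 = need_a.pop(0), need_a.pop(0)
            a_pairs[frozenset((e1, e2))] = color
        while len(need_b) >= 2:
            e1, e2 = need_b.pop(0), need_b.pop(0)
            pair = frozenset((e1, e2))
            b_pairs.append(pair)
            edge_origin[pair] = ("loop", None)
        if need_a and need_b:
            bridge = fresh()
            a_pairs[frozenset((need_a[0], bridge))] = color
            pair = frozenset((bridge, need_b[0]))
            b_pairs.append(pair)
            edge_origin[pair] = ("loop", None)
            need_a.clear()
            need_b.clear()
        if need_a or need_b:
            raise MlsInternalError(f"unmatched path endpoint of color {color!r}")

    a_hat = Genome(a_pairs)
    b_hat = Genome(b_pairs)
    col_hat = Coloring(a_pairs, col.palette)
    if a_hat.extremities != b_hat.extremities:
        raise MlsInternalError("capped genomes cover different universes")

    art = frozenset(artificial)
    telomeric = frozenset(p for p in a_hat.adjacencies if p <= art)

    # non-loop equality check against J'
    j_hat = build_junction_graph(a_hat, b_hat, col_hat)
    nl_hat = sorted(
        tuple(sorted((u, v), key=repr)) for u, v in j_hat.edges.values() if u != v
    )
    nl_prime = sorted(
        tuple(sorted((u, v), key=repr)) for u, v in jprime.edges.values() if u != v
    )
    if nl_hat != nl_prime:
        raise MlsInternalError("capped junction graph is not non-loop equal to J'")

    return CappedInstance(a_hat, b_hat, col_hat, art, telomeric, edge_origin, jprime)


# ---------------------------------------------------------------------------
# Sorting the capped instance and projecting back
# ---------------------------------------------------------------------------


def _sortable_cycles(capped: CappedInstance, packing: CyclePacking):
    """Cycles of the capped junction graph needing 2-breaks, as
    (b_hat pair sequence, color walk) with pair i joining walk[i], walk[i+1].
    """
    j = packing.host
    dup_pair_of = {
        origin[1]: pair
        for pair, origin in capped.edge_origin.items()
        if origin[0] == "dup"
    }
    cycles = []
    for cyc in packing.cycles:
        if len(cyc) >= 2:
            cycles.append((list(cyc.edges), list(cyc.walk)))
    for eid in sorted(packing.uncovered_edges, key=lambda e: sorted(e)):
        u, v = j.edges[eid]
        if u == v:  # pragma: no cover - loops are always packable
            raise MlsInternalError("uncovered loop edge")
        cycles.append(([eid, dup_pair_of[eid]], [u, v]))
    cycles.sort(key=lambda c: sorted(sorted(p) for p in c[0]))
    return cycles


def _sort_capped(capped: CappedInstance, packing: CyclePacking):
    """Emit one non-local DCJ per 2-break until the junction graph of the
    capped instance is terminal, then zero-cost moves until it equals B-hat.
    """
    g, c = capped.a_hat, capped.col_hat
    moves: list[DcjMove] = []

    def locate(bpair: Adjacency, color, index):
        """The extremity of a b_hat pair currently in an a_hat pair of ``color``."""
        hits = [x for x in sorted(bpair) if c.of(index[x]) == color]
        if len(hits) != 1:
            raise MlsInternalError(
                f"pair {set(bpair)} has {len(hits)} extremities at color {color!r}"
            )
        return hits[0]

    art = capped.artificial

    def ensure_projectable(bx, dx, v_mid, v_hi):
        """Give a drift-prone swap a real stay-behind partner.

        Swapping two extremities whose pairs both keep only artificial
        partners would change colors of external adjacencies of the
        original genome without any projectable move.  A zero-cost merge
        with a same-colored pair holding a real extremity (junction graph
        unchanged) makes the subsequent swap structural downstream.
        """
        nonlocal g, c
        index = g.index()
        p, q = index[bx], index[dx]
        (b_stay,) = tuple(p - {bx})
        (d_stay,) = tuple(q - {dx})
        drifts = (
            (bx not in art or dx not in art)
            and b_stay in art
            and d_stay in art
        )
        if not drifts:
            return
        for color, pair0, moved in ((v_hi, q, dx), (v_mid, p, bx)):
            cands = [
                r
                for r in g.adjacencies
                if r not in (p, q) and c.of(r) == color and any(x not in art for x in r)
            ]
            if not cands:
                continue
            r_pair = sorted(cands, key=sorted)[0]
            rx = min(x for x in r_pair if x not in art)
            mv0 = DcjMove(
                consumed=((pair0, color), (r_pair, color)),
                produced=(
                    (frozenset({moved, rx}), color),
                    ((pair0 - {moved}) | (r_pair - {rx}), color),
                ),
            )
            g, c, cost0 = apply_move(g, c, mv0)
            if cost0 != 0:
                raise MlsInternalError("pre-merge move was not local")
            moves.append(mv0)
            return

    for bpairs, walk in _sortable_cycles(capped, packing):
        l = len(bpairs)
        chain = bpairs[0]
        for i in range(1, l):
            v_mid, v_hi = walk[i], walk[(i + 1) % l]
            index = g.index()
            bx = locate(chain, v_mid, index)
            dx = locate(bpairs[i], v_hi, index)
            ensure_projectable(bx, dx, v_mid, v_hi)
            index = g.index()
            p, q = index[bx], index[dx]
            mv = DcjMove(
                consumed=((p, v_mid), (q, v_hi)),
                produced=(
                    (frozenset({bx}) | (q - {dx}), v_hi),
                    ((p - {bx}) | frozenset({dx}), v_mid),
                ),
            )
            g, c, cost = apply_move(g, c, mv)
            if cost != 1:
                raise MlsInternalError("sorting move was not non-local")
            moves.append(mv)

    # local completion: junction graph is terminal, so adjacency-graph
    # components are monochromatic; assemble B-hat with zero-cost moves.
    while True:
        missing = sorted(
            (adj for adj in capped.b_hat.adjacencies if adj not in g.adjacencies),
            key=sorted,
        )
        if not missing:
            break
        adj = missing[0]
        px, qx = sorted(adj)
        index = g.index()
        p, q = index[px], index[qx]
        x, y = c.of(p), c.of(q)
        if x != y or p == q:
            raise MlsInternalError("junction graph not terminal before completion")
        rest = (p - {px}) | (q - {qx})
        mv = DcjMove(
            consumed=((p, x), (q, x)),
            produced=((frozenset({px, qx}), x), (rest, x)),
        )
        g, c, cost = apply_move(g, c, mv)
        if cost != 0:
            raise MlsInternalError("completion move was not local")
        moves.append(mv)

    if g.adjacencies != capped.b_hat.adjacencies:
        raise MlsInternalError("capped scenario did not reach B-hat")
    return moves


def _project_scenario(
    a: Genome, col: Coloring, capped: CappedInstance, capped_moves: Sequence[DcjMove]
):
    """Project a scenario on the capped genomes down to the originals.

    Telomeric pairs vanish; a pair with one artificial extremity projects to
    the external adjacency of its real extremity.  Moves whose projection
    leaves the genome unchanged are dropped; produced colors are chosen to
    track the capped coloring whenever a rewrite template allows it.
    """
    art = capped.artificial

    def img(pair: Adjacency):
        real = frozenset(x for x in pair if x not in art)
        return real or None

    cur, cur_col = a, col
    out: list[DcjMove] = []
    for mv in capped_moves:
        before: dict = {}
        after: dict = {}
        for pair, color in mv.consumed:
            ip = img(pair)
            if ip is not None:
                before[ip] = color
        for pair, color in mv.produced:
            ip = img(pair)
            if ip is not None:
                after[ip] = color
        if set(before) == set(after):
            continue
        consumed = tuple((adj, cur_col.of(adj)) for adj in sorted(before, key=sorted))
        prods = sorted(after, key=sorted)
        ccols = [color for _, color in consumed]
        want = [after[adj] for adj in prods]
        if len(consumed) == 1:  # split: one product keeps x, the other is free
            x = ccols[0]
            if want[0] == x:
                assign = (x, want[1])
            elif want[1] == x:
                assign = (want[0], x)
            else:
                assign = (x, want[1])
        elif len(prods) == 1:  # join: product color from the consumed colors
            assign = (want[0] if want[0] in ccols else ccols[0],)
        else:  # pair-pair / pair-telomere: produced colors permute consumed
            if sorted(map(repr, want)) == sorted(map(repr, ccols)):
                assign = tuple(want)
            else:
                fwd = sum(int(w == cc) for w, cc in zip(want, ccols))
                rev = sum(int(w == cc) for w, cc in zip(want, ccols[::-1]))
                assign = tuple(ccols) if fwd >= rev else tuple(ccols[::-1])
        move = DcjMove(consumed=consumed, produced=tuple(zip(prods, assign)))
        cur, cur_col, _ = apply_move(cur, cur_col, move)
        out.append(move)
    return tuple(out), cur, cur_col


def _scenario_pipeline(
    a: Genome, b: Genome, col: Coloring, packing: CyclePacking
):
    capped = cap_instance(a, b, col, packing)
    capped_moves = _sort_capped(capped, packing)
    scenario, final, _ = _project_scenario(a, col, capped, capped_moves)
    if final.adjacencies != b.adjacencies:
        raise MlsInternalError("projected scenario does not reach B")
    return scenario


def min_local_scenario(
    a: Genome, b: Genome, col: Coloring, config: PackingConfig | None = None
) -> MlsResult:
    """Exact MLS with an explicit scenario: ``e(J) - c(J)`` non-local moves."""
    _check_instance(a, b, col)
    j = build_junction_graph(a, b, col)
    packing = mecp_exact(j, config)
    cost = j.n_edges - len(packing)
    scenario = _scenario_pipeline(a, b, col, packing)
    achieved = replay(a, col, scenario)
    if achieved.n_nonlocal != cost:
        raise MlsInternalError(
            f"constructed scenario costs {achieved.n_nonlocal}, expected {cost}"
        )
    return MlsResult(
        cost=cost,
        junction_edges=j.n_edges,
        packing=packing,
        lower_bound=_lower_bound(j),
        scenario=scenario,
    )


def approx_scenario(a: Genome, b: Genome, col: Coloring) -> MlsResult:
    """3/2-approximate MLS from the loop/digon packing; no cycle enumeration.

    The reported cost ``e - c1 - c2`` is an upper bound within factor 3/2 of
    the optimum; the attached scenario replays with at most that many
    non-local moves.
    """
    _check_instance(a, b, col)
    j = build_junction_graph(a, b, col)
    packing = greedy_loops_digons_packing(j)
    cost = j.n_edges - len(packing)
    scenario = _scenario_pipeline(a, b, col, packing)
    achieved = replay(a, col, scenario)
    if achieved.n_nonlocal > cost:
        raise MlsInternalError(
            f"approximate scenario costs {achieved.n_nonlocal} > bound {cost}"
        )
    return MlsResult(
        cost=cost,
        junction_edges=j.n_edges,
        packing=packing,
        lower_bound=_lower_bound(j),
        scenario=scenario,
    )
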