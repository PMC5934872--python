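"""Genomes as adjacency sets, colorings, and colored DCJ moves.

A genome on a set of syntenic blocks is represented by its adjacencies:
an *internal* adjacency is an unordered pair of block extremities that are
neighbors on a chromosome, an *external* adjacency is a single extremity
sitting at the end of a linear chromosome.  Every extremity occurs in
exactly one adjacency.

A coloring partitions the adjacencies of one genome into classes (e.g. 3D
chromatin neighborhoods).  A DCJ move acting on adjacencies of one color is
*local* and free; a move acting across colors is *non-local* and costs one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

Adjacency = frozenset  # frozenset of 1 or 2 positive int extremities

__all__ = [
    "Adjacency",
    "adjacency",
    "Genome",
    "Coloring",
    "DcjMove",
    "Scenario",
    "ReplayResult",
    "BlockGenome",
    "Chromosome",
    "GenomeError",
    "parse_block_genome",
    "block_to_adjacency",
    "chromosomes_from_adjacencies",
    "co_rename",
    "apply_move",
    "replay",
]


class GenomeError(ValueError):
    """Raised for malformed genomes, colorings or inapplicable moves."""


def adjacency(a: int, b: int | None = None) -> Adjacency:
    """Build an adjacency from one (external) or two (internal) extremities."""
    if b is None:
        return frozenset((a,))
    if a == b:
        raise GenomeError(f"adjacency extremities must be distinct: {a}")
    return frozenset((a, b))


def _check_adjacency(adj) -> Adjacency:
    adj = frozenset(adj)
    if not 1 <= len(adj) <= 2:
        raise GenomeError(f"adjacency must have 1 or 2 extremities: {set(adj)}")
    for x in adj:
        if not isinstance(x, int) or x < 1:
            raise GenomeError(f"extremity labels must be positive integers: {x!r}")
    return adj


@dataclass(frozen=True)
class Genome:
    """A set of adjacencies in which every extremity occurs exactly once."""

    adjacencies: frozenset

    def __init__(self, adjacencies: Iterable):
        adjs = frozenset(_check_adjacency(a) for a in adjacencies)
        seen: set[int] = set()
        for adj in adjs:
            for x in adj:
                if x in seen:
                    raise GenomeError(f"extremity {x} occurs in more than one adjacency")
                seen.add(x)
        object.__setattr__(self, "adjacencies", adjs)

    @property
    def extremities(self) -> frozenset:
        return frozenset(x for adj in self.adjacencies for x in adj)

    @property
    def n_internal(self) -> int:
        return sum(1 for a in self.adjacencies if len(a) == 2)

    @property
    def n_external(self) -> int:
        return sum(1 for a in self.adjacencies if len(a) == 1)

    def containing(self, extremity: int) -> Adjacency:
        for adj in self.adjacencies:
            if extremity in adj:
                return adj
        raise GenomeError(f"extremity {extremity} not present in genome")

    def index(self) -> dict:
        """Map each extremity to the adjacency containing it."""
        return {x: adj for adj in self.adjacencies for x in adj}

    def __contains__(self, adj) -> bool:
        return frozenset(adj) in self.adjacencies

    def __iter__(self):
        return iter(self.adjacencies)

    def __len__(self) -> int:
        return len(self.adjacencies)


def _sorted_adjs(adjs: Iterable[Adjacency]):
    return sorted(adjs, key=lambda a: sorted(a))


@dataclass(frozen=True)
class Coloring:
    """A total map from the adjacencies of one genome to color labels."""

    assignment: Mapping
    palette: frozenset = None  # type: ignore[assignment]

    def __init__(self, assignment: Mapping, palette: Iterable | None = None):
        assignment = {frozenset(k): v for k, v in dict(assignment).items()}
        used = set(assignment.values())
        pal = frozenset(used if palette is None else palette)
        if not used <= pal:
            raise GenomeError(f"colors {used - pal} missing from palette")
        object.__setattr__(self, "assignment", assignment)
        object.__setattr__(self, "palette", pal)

    def of(self, adj) -> object:
        try:
            return self.assignment[frozenset(adj)]
        except KeyError:
            raise GenomeError(f"adjacency {set(adj)} has no color") from None

    def validate_total(self, genome: Genome) -> None:
        missing = genome.adjacencies - set(self.assignment)
        if missing:
            raise GenomeError(f"uncolored adjacencies: {[set(a) for a in _sorted_adjs(missing)]}")

    def is_surjective(self) -> bool:
        return set(self.assignment.values()) == set(self.palette)

    def items(self):
        return self.assignment.items()

    def recolored(self, changes: Mapping, removed: Iterable = ()) -> "Coloring":
        new = dict(self.assignment)
        for adj in removed:
            new.pop(frozenset(adj), None)
        for adj, col in changes.items():
            new[frozenset(adj)] = col
        return Coloring(new, self.palette | set(changes.values()))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Coloring)
            and dict(self.assignment) == dict(other.assignment)
            and self.palette == other.palette
        )

    def __hash__(self) -> int:
        return hash((frozenset(self.assignment.items()), self.palette))


@dataclass(frozen=True)
class DcjMove:
    """One colored DCJ rewrite.

    ``consumed`` and ``produced`` are tuples of ``(adjacency, color)`` pairs
    matching one of the four rewrite templates:

    * pair-pair:     ({a,b},x),({c,d},y) -> ({a,c},x),({b,d},y) (colors may swap)
    * pair-telomere: ({a,b},x),({c},y)   -> ({a,c},x),({b},y)   (colors may swap)
    * split:         ({a,b},x)           -> ({a},x),({b},z)      with any color z
    * join:          ({a},x),({b},y)     -> ({a,b},x) or ({a,b},y)

    The color attribution of the produced adjacencies is recorded explicitly
    rather than left implicit, since either branch of a template is legal.
    """

    consumed: tuple
    produced: tuple

    def __post_init__(self):
        consumed = tuple((frozenset(a), c) for a, c in self.consumed)
        produced = tuple((frozenset(a), c) for a, c in self.produced)
        object.__setattr__(self, "consumed", consumed)
        object.__setattr__(self, "produced", produced)
        self._validate()

    def _validate(self) -> None:
        cons = [a for a, _ in self.consumed]
        prod = [a for a, _ in self.produced]
        for a in cons + prod:
            _check_adjacency(a)
        c_ext = sorted(x for a in cons for x in a)
        p_ext = sorted(x for a in prod for x in a)
        if c_ext != p_ext:
            raise GenomeError(f"extremity multiset not conserved: {c_ext} -> {p_ext}")
        kind = self.kind
        ccols = [c for _, c in self.consumed]
        pcols = [c for _, c in self.produced]
        if kind == "split":
            (ab, x) = self.consumed[0]
            if x not in pcols:
                raise GenomeError("split must keep the consumed color on one product")
        elif kind == "join":
            if pcols[0] not in ccols:
                raise GenomeError("join must attribute one of the consumed colors")
        else:  # pair-pair / pair-telomere
            if sorted(map(repr, ccols)) != sorted(map(repr, pcols)):
                raise GenomeError(f"produced colors {pcols} are not a permutation of {ccols}")
            a, b = cons
            if a == b:
                raise GenomeError("consumed adjacencies must be distinct")
            if kind == "pair-pair":
                # a valid re-matching takes one extremity from each consumed pair
                if not all(len(r & a) == 1 and len(r & b) == 1 for r in prod):
                    raise GenomeError("invalid pair-pair re-matching")
            else:  # pair-telomere
                pair = a if len(a) == 2 else b
                tel = b if len(b) == 1 else a
                sizes = sorted(len(r) for r in prod)
                if sizes != [1, 2]:
                    raise GenomeError("pair-telomere must produce one pair and one telomere")
                new_pair = next(r for r in prod if len(r) == 2)
                if not (len(new_pair & pair) == 1 and tel < new_pair):
                    raise GenomeError("invalid pair-telomere re-matching")

    @property
    def kind(self) -> str:
        nc, np_ = len(self.consumed), len(self.produced)
        if nc == 1 and np_ == 2:
            return "split"
        if nc == 2 and np_ == 1:
            return "join"
        if nc == 2 and np_ == 2:
            sizes = sorted(len(a) for a, _ in self.consumed)
            if sizes == [2, 2]:
                return "pair-pair"
            if sizes == [1, 2]:
                return "pair-telomere"
            if sizes == [1, 1]:
                raise GenomeError("two telomeres can only be joined")
        raise GenomeError("unrecognized move shape")

    @property
    def cost(self) -> int:
        """1 for a non-local move, 0 for a local one."""
        if self.kind == "split":
            x = self.consumed[0][1]
            return 0 if all(c == x for _, c in self.produced) else 1
        (x, y) = (self.consumed[0][1], self.consumed[1][1])
        return 0 if x == y else 1


Scenario = tuple  # ordered sequence of DcjMove


@dataclass(frozen=True)
class ReplayResult:
    genome: Genome
    coloring: Coloring
    total_cost: int
    n_nonlocal: int
    n_local: int


def apply_move(genome: Genome, coloring: Coloring, move: DcjMove):
    """Apply one colored DCJ; returns ``(genome', coloring', cost)``.

    Raises :class:`GenomeError` if a consumed adjacency is absent or its
    recorded color disagrees with the current coloring.
    """
    for adj, col in move.consumed:
        if adj not in genome.adjacencies:
            raise GenomeError(f"consumed adjacency {set(adj)} absent from genome")
        if coloring.of(adj) != col:
            raise GenomeError(
                f"color mismatch on {set(adj)}: move says {col!r}, "
                f"coloring says {coloring.of(adj)!r}"
            )
    removed = {adj for adj, _ in move.consumed}
    new_adjs = (genome.adjacencies - removed) | {adj for adj, _ in move.produced}
    new_genome = Genome(new_adjs)
    new_coloring = coloring.recolored(dict(move.produced), removed=removed)
    return new_genome, new_coloring, move.cost


def replay(genome: Genome, coloring: Coloring, scenario: Sequence[DcjMove]) -> ReplayResult:
    """Replay a scenario move by move, accumulating the non-local cost."""
    g, c = genome, coloring
    nonlocal_ = 0
    for k, move in enumerate(scenario):
        try:
            g, c, cost = apply_move(g, c, move)
        except GenomeError as err:
            raise GenomeError(f"scenario inapplicable at step {k}: {err}") from err
        nonlocal_ += cost
    n = len(scenario)
    return ReplayResult(g, c, nonlocal_, nonlocal_, n - nonlocal_)


# ---------------------------------------------------------------------------
# Block-level genomes (GRIMM-like signed permutations)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chromosome:
    blocks: tuple  # signed block identifiers; sign -1 encoded by leading "-"
    circular: bool = False


@dataclass(frozen=True)
class BlockGenome:
    """Ordered chromosomes of signed block identifiers.

    Block identifiers are strings (purely numeric ones compare numerically);
    each identifier occurs exactly once across all chromosomes.
    """

    chromosomes: tuple

    def __post_init__(self):
        seen: set[str] = set()
        for chrom in self.chromosomes:
            if not chrom.blocks:
                raise GenomeError("empty chromosome")
            for b in chrom.blocks:
                name = b.lstrip("-")
                if not name:
                    raise GenomeError(f"unknown block token {b!r}")
                if name in seen:
                    raise GenomeError(f"duplicate block {name!r}")
                seen.add(name)

    @property
    def block_names(self) -> tuple:
        names = [b.lstrip("-") for ch in self.chromosomes for b in ch.blocks]
        return tuple(sorted(names, key=_block_sort_key))

    @property
    def n_linear(self) -> int:
        return sum(1 for ch in self.chromosomes if not ch.circular)


def _block_sort_key(name: str):
    return (0, int(name), "") if name.isdigit() else (1, 0, name)


_TOKEN = re.compile(r"^-?[A-Za-z0-9_.]+$")


def parse_block_genome(text: str) -> BlockGenome:
    """Parse a GRIMM-like document.

    Chromosome lines are whitespace-separated signed block tokens terminated
    by ``$`` (linear) or ``@`` (circular); ``#`` starts a comment.
    """
    chromosomes = []
    pending: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        for tok in tokens:
            if tok in ("$", "@"):
                if not pending:
                    raise GenomeError(f"line {lineno}: empty chromosome")
                chromosomes.append(Chromosome(tuple(pending), circular=(tok == "@")))
                pending = []
            elif _TOKEN.match(tok):
                pending.append(tok)
            else:
                raise GenomeError(f"line {lineno}: unknown token {tok!r}")
    if pending:
        raise GenomeError("chromosome lacks a '$' or '@' terminator")
    if not chromosomes:
        raise GenomeError("no chromosomes found")
    return BlockGenome(tuple(chromosomes))


def format_block_genome(g: BlockGenome) -> str:
    lines = []
    for ch in g.chromosomes:
        lines.append(" ".join(ch.blocks) + (" @" if ch.circular else " $"))
    return "\n".join(lines) + "\n"


def block_to_adjacency(g: BlockGenome):
    """Convert a block genome to its adjacency set.

    Block *i* (in sorted identifier order, 1-based) gets tail extremity
    ``2i-1`` and head extremity ``2i``.  Returns ``(genome, names)`` where
    ``names`` maps each integer extremity to a ``"<block>_t"`` / ``"<block>_h"``
    label (and back).
    """
    order = {name: i for i, name in enumerate(g.block_names, 1)}
    names: dict = {}
    for name, i in order.items():
        names[2 * i - 1] = f"{name}_t"
        names[f"{name}_t"] = 2 * i - 1
        names[2 * i] = f"{name}_h"
        names[f"{name}_h"] = 2 * i

    def ends(token: str):
        name = token.lstrip("-")
        i = order[name]
        tail, head = 2 * i - 1, 2 * i
        return (head, tail) if token.startswith("-") else (tail, head)

    adjs = []
    for ch in g.chromosomes:
        lefts_rights = [ends(b) for b in ch.blocks]
        for (_, right), (left, _) in zip(lefts_rights, lefts_rights[1:]):
            adjs.append(adjacency(right, left))
        first_left = lefts_rights[0][0]
        last_right = lefts_rights[-1][1]
        if ch.circular:
            if len(ch.blocks) == 1:
                adjs.append(adjacency(first_left, last_right))
            else:
                adjs.append(adjacency(last_right, first_left))
        else:
            adjs.append(adjacency(first_left))
            adjs.append(adjacency(last_right))
    return Genome(adjs), names


def chromosomes_from_adjacencies(genome: Genome, names: Mapping) -> BlockGenome:
    """Rebuild chromosomes from an adjacency set (inverse of block conversion).

    The result is canonical: each linear chromosome is read from its
    smaller-labeled end, circular chromosomes start at their smallest
    extremity, and chromosomes are sorted by first block.
    """
    partner = {}
    for x in genome.extremities:
        partner[x] = x + 1 if x % 2 == 1 else x - 1  # other end of the block
    index = genome.index()
    unvisited = set(genome.extremities)
    chromosomes = []
    while unvisited:
        start = min(unvisited)
        adj = index[start]
        # prefer starting from a telomere so linear chromosomes are walked end to end
        telomeres = [x for x in sorted(unvisited) if len(index[x]) == 1]
        if telomeres:
            start = telomeres[0]
        blocks = []
        x = start
        circular = not telomeres
        while True:
            unvisited.discard(x)
            name = names[x]
            base, end = name.rsplit("_", 1)
            blocks.append(base if end == "t" else f"-{base}")
            y = partner[x]
            unvisited.discard(y)
            nxt_adj = index[y]
            if len(nxt_adj) == 1:
                break
            (x,) = nxt_adj - {y}
            if x not in unvisited:
                break
        chromosomes.append(Chromosome(tuple(blocks), circular=circular))
    chromosomes.sort(key=lambda ch: _block_sort_key(ch.blocks[0].lstrip("-")))
    return BlockGenome(tuple(chromosomes))


def co_rename(a: Genome, b: Genome):
    """Relabel both genomes so that A takes the canonical pair-coded form
    ``{1,2},...,{2n-1,2n},{2n+1},...,{2n+2m}``.

    A's internal adjacencies are ordered by smallest member, then externals
    ascending; the same bijection is applied to B.  Returns
    ``(a', b', mapping)`` with ``mapping[old] = new`` (invert as needed).
    """
    if a.extremities != b.extremities:
        raise GenomeError("genomes are over different extremity universes")
    mapping: dict[int, int] = {}
    nxt = 1
    for adj in _sorted_adjs(x for x in a.adjacencies if len(x) == 2):
        for x in sorted(adj):
            mapping[x] = nxt
            nxt += 1
    for adj in _sorted_adjs(x for x in a.adjacencies if len(x) == 1):
        (x,) = adj
        mapping[x] = nxt
        nxt += 1
    a2 = Genome(frozenset(mapping[x] for x in adj) for adj in a.adjacencies)
    b2 = Genome(frozenset(mapping[x] for x in adj) for adj in b.adjacencies)
    return a2, b2, mapping
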