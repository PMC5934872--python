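"""Text formats: genomes, colorings, scenarios, multigraphs, Hi-C tables.

Genomes travel either as GRIMM-like signed permutations (``$`` ends a
linear chromosome, ``@`` a circular one, ``#`` comments) or as adjacency
sets, one adjacency per line — ``a b`` or ``a``, with an optional trailing
color label turning the file into a combined genome+coloring.  Scenarios
are one move per line in the form::

    (1,2|y),(3,4|z) -> (1,4|y),(3,2|z) cost=1

with telomeres written ``(5|t)``.  Hi-C data is a bin table TSV
(chrom, start, end) plus either a 3-column contact list (bin-i, bin-j,
count) or dense per-chromosome-pair matrices.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    Adjacency,
    BlockGenome,
    Coloring,
    DcjMove,
    Genome,
    GenomeError,
    format_block_genome,
    parse_block_genome,
)
from .graphs import Multigraph
from .hic import HicDataset

__all__ = [
    "read_genome",
    "write_genome",
    "read_adjacency_file",
    "write_adjacency_file",
    "format_scenario",
    "parse_scenario",
    "read_multigraph",
    "write_multigraph",
    "read_hic",
    "read_hic_dense",
    "read_regions_bed",
]


def read_genome(path) -> BlockGenome:
    return parse_block_genome(Path(path).read_text())


def write_genome(path, g: BlockGenome) -> None:
    Path(path).write_text(format_block_genome(g))


def parse_adjacency_text(text: str):
    """Parse the adjacency-set format; returns ``(genome, coloring_or_None)``.

    A trailing non-integer token on a line is that adjacency's color; either
    all lines carry colors or none do.
    """
    adjs = []
    colors = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        ints = []
        color = None
        for tok in tokens:
            if re.fullmatch(r"\d+", tok) and color is None:
                ints.append(int(tok))
            elif color is None:
                color = tok
            else:
                raise GenomeError(f"line {lineno}: trailing token {tok!r}")
        if not 1 <= len(ints) <= 2:
            raise GenomeError(f"line {lineno}: expected 1 or 2 extremities")
        adj = frozenset(ints)
        if len(adj) != len(ints):
            raise GenomeError(f"line {lineno}: repeated extremity")
        adjs.append(adj)
        if color is not None:
            colors[adj] = color
    genome = Genome(adjs)
    if colors and len(colors) != len(adjs):
        raise GenomeError("either every adjacency or none must carry a color")
    return genome, (Coloring(colors) if colors else None)


def read_adjacency_file(path):
    return parse_adjacency_text(Path(path).read_text())


def write_adjacency_file(path, genome: Genome, coloring: Coloring | None = None) -> None:
    """Color tokens must be non-numeric in the file format (extremities are
    bare integers), so integer color labels are written as ``c<label>``."""
    lines = []
    for adj in sorted(genome.adjacencies, key=sorted):
        fields = [str(x) for x in sorted(adj)]
        if coloring is not None:
            tok = str(coloring.of(adj))
            fields.append(f"c{tok}" if tok.isdigit() else tok)
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Scenario reports
# ---------------------------------------------------------------------------


def _fmt_colored(adj: Adjacency, color) -> str:
    return f"({','.join(str(x) for x in sorted(adj))}|{color})"


def format_move(move: DcjMove) -> str:
    lhs = ",".join(_fmt_colored(a, c) for a, c in move.consumed)
    rhs = ",".join(_fmt_colored(a, c) for a, c in move.produced)
    return f"{lhs} -> {rhs} cost={move.cost}"


def format_scenario(scenario: Sequence[DcjMove]) -> str:
    return "\n".join(format_move(m) for m in scenario) + ("\n" if scenario else "")


_COLORED = re.compile(r"\((\d+)(?:,(\d+))?\|([^)]*)\)")


def parse_scenario(text: str):
    """Parse a scenario report; colors are read back as strings."""
    moves = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        lhs, _, rest = line.partition("->")
        rhs = rest.rsplit("cost=", 1)[0]
        consumed = tuple(
            (frozenset(int(x) for x in (m[0], m[1]) if x), m[2])
            for m in _COLORED.findall(lhs)
        )
        produced = tuple(
            (frozenset(int(x) for x in (m[0], m[1]) if x), m[2])
            for m in _COLORED.findall(rhs)
        )
        if not consumed or not produced:
            raise GenomeError(f"unparseable scenario line: {line!r}")
        moves.append(DcjMove(consumed, produced))
    return tuple(moves)


# ---------------------------------------------------------------------------
# Multigraphs
# ---------------------------------------------------------------------------


def write_multigraph(path, g: Multigraph) -> None:
    lines = [f"{u} {v} {eid}" for eid, (u, v) in sorted(g.edges.items(), key=repr)]
    lines += [f"{v}" for v in sorted(g.vertices, key=repr) if g.degree(v) == 0]
    Path(path).write_text("\n".join(lines) + "\n")


def read_multigraph(path) -> Multigraph:
    """Edge-list format: ``u v id`` per line (loops as ``u u id``); a line
    with a single token declares an isolated vertex."""
    g = Multigraph()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) == 1:
            g.add_vertex(tokens[0])
        elif len(tokens) == 3:
            g.add_edge(tokens[0], tokens[1], tokens[2])
        else:
            raise ValueError(f"line {lineno}: expected 'u v id' or a lone vertex")
    return g


# ---------------------------------------------------------------------------
# Hi-C
# ---------------------------------------------------------------------------


def _read_bins(bins_path) -> pd.DataFrame:
    bins = pd.read_csv(bins_path, sep="\t")
    required = {"chrom", "start", "end"}
    if not required <= set(bins.columns):
        raise ValueError(f"bin table needs columns {sorted(required)}")
    return bins.reset_index(drop=True)


def read_hic(bins_path, contacts_path) -> HicDataset:
    """Bin table TSV plus a 3-column contact list (bin_i, bin_j, count)."""
    bins = _read_bins(bins_path)
    n = len(bins)
    contacts = pd.read_csv(contacts_path, sep="\t", header=None, comment="#")
    if contacts.shape[1] != 3:
        raise ValueError("contact list must have 3 columns: bin_i bin_j count")
    raw = np.zeros((n, n))
    for i, j, v in contacts.itertuples(index=False):
        raw[int(i), int(j)] += float(v)
        if i != j:
            raw[int(j), int(i)] += float(v)
    return HicDataset(bins, raw)


def read_hic_dense(bins_path, matrix_dir) -> HicDataset:
    """Bin table plus dense per-chromosome-pair TSVs named ``C1__C2.tsv``.

    Missing pairs are treated as all-zero blocks; intra files must be
    symmetric.
    """
    bins = _read_bins(bins_path)
    n = len(bins)
    raw = np.zeros((n, n))
    idx = {
        c: np.flatnonzero((bins["chrom"] == c).to_numpy())
        for c in bins["chrom"].unique()
    }
    for path in sorted(Path(matrix_dir).glob("*.tsv")):
        c1, sep, c2 = path.stem.partition("__")
        if not sep or c1 not in idx or c2 not in idx:
            raise ValueError(f"matrix file {path.name} does not name two chromosomes")
        block = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        if block.shape != (len(idx[c1]), len(idx[c2])):
            raise ValueError(f"{path.name}: shape {block.shape} does not match bins")
        raw[np.ix_(idx[c1], idx[c2])] = block
        raw[np.ix_(idx[c2], idx[c1])] = block.T
    return HicDataset(bins, raw)


def read_regions_bed(path, genome: Genome) -> dict:
    """BED of breakpoint regions; the name field identifies the adjacency as
    ``a-b`` (internal) or ``a`` (external).  Returns adjacency -> region.
    """
    regions = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"line {lineno}: BED needs chrom start end name")
        chrom, start, end, name = fields[:4]
        exts = frozenset(int(x) for x in name.split("-"))
        if exts not in genome.adjacencies:
            raise GenomeError(f"line {lineno}: {name!r} is not an adjacency of A")
        regions[exts] = (chrom, int(start), int(end))
    missing = genome.adjacencies - set(regions)
    if missing:
        raise GenomeError(f"{len(missing)} adjacencies lack breakpoint regions")
    return regions
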