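"""Colorings of adjacencies from Hi-C chromatin contact data.

Hi-C yields binned contact-frequency matrices that proxy 3D proximity.
Because raw intra-chromosomal contacts decay roughly as a power law in 1D
distance, two normalizations are applied before contacts are used as a
similarity between breakpoint regions:

* intra-chromosomal: ``INTRA_ij = H_ij / averageAtDist(|i - j|)`` where
  ``averageAtDist(d)`` is the mean raw contact over all same-chromosome bin
  pairs at offset d, pooled across chromosomes;
* inter-chromosomal: ``INTER_ij = H_ij / (interaction_i * interaction_j /
  interaction_all)`` with ``interaction_x`` the total raw contact of bin x,
  which boosts loci with few contacts overall.

The similarity drives a weight-maximizing k-medoids clustering of the
adjacencies of one genome; linear (1D-contiguous) and uniformly random
colorings serve as baselines, and *divergence from linearity* quantifies
how far any coloring is from a union of contiguous chromosome segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    Adjacency,
    BlockGenome,
    Coloring,
    Genome,
    GenomeError,
    block_to_adjacency,
)

__all__ = [
    "HicDataset",
    "SimilarityTable",
    "ColoringQuality",
    "normalize_intra",
    "normalize_inter",
    "adjacency_similarity",
    "kmedoids_coloring",
    "linear_coloring",
    "random_coloring",
    "divergence_from_linearity",
    "clustering_weight",
    "adjacency_order",
]


@dataclass(frozen=True)
class HicDataset:
    """Binned contact matrices with 0-based half-open bin coordinates.

    ``bins`` has columns ``chrom``, ``start``, ``end`` and is ordered so
    that row *i* is matrix index *i*; ``raw`` is the full symmetric contact
    matrix.  ``intra``/``inter`` hold the normalized values (NaN where the
    normalization is undefined or does not apply).
    """

    bins: pd.DataFrame
    raw: np.ndarray
    intra: np.ndarray | None = None
    inter: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.bins)
        if self.raw.shape != (n, n):
            raise ValueError(f"matrix shape {self.raw.shape} does not match {n} bins")
        if not np.allclose(self.raw, self.raw.T):
            raise ValueError("contact matrix must be symmetric")
        if (self.raw < 0).any():
            raise ValueError("contact matrix must be nonnegative")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_of(self, i: int) -> str:
        return self.bins.iloc[i]["chrom"]

    def same_chrom(self) -> np.ndarray:
        chroms = self.bins["chrom"].to_numpy()
        return chroms[:, None] == chroms[None, :]

    def bin_at(self, chrom: str, pos: int) -> int:
        hits = self.bins[
            (self.bins["chrom"] == chrom)
            & (self.bins["start"] <= pos)
            & (pos < self.bins["end"])
        ]
        if hits.empty:
            raise ValueError(f"position {chrom}:{pos} outside binned coordinates")
        return int(hits.index[0])


def normalize_intra(h: HicDataset) -> HicDataset:
    """Divide each intra-chromosomal entry by the mean contact at its 1D
    bin offset, pooled over all chromosomes.

    Offsets with no observations stay undefined (NaN) rather than zero; by
    construction the mean of INTRA over all pairs at each defined offset is 1.
    """
    if h.n_bins == 0:
        raise ValueError("empty dataset")
    same = h.same_chrom()
    n = h.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    intra = np.full((n, n), np.nan)
    for d in range(n):
        mask = same & (dist == d)
        if not mask.any():
            continue
        avg = h.raw[mask].mean()
        if avg > 0:
            intra[mask] = h.raw[mask] / avg
    return replace(h, intra=intra)


def normalize_inter(h: HicDataset) -> HicDataset:
    """Inter-chromosomal normalization by expected coverage product.

    Invariant under a global rescaling of the raw matrix.  Bins with zero
    total interaction get NaN rather than a division by zero.
    """
    if h.n_bins == 0:
        raise ValueError("empty dataset")
    interaction = h.raw.sum(axis=1)
    total = h.raw.sum()
    expected = np.outer(interaction, interaction) / total if total > 0 else None
    inter = np.full((h.n_bins, h.n_bins), np.nan)
    if expected is not None:
        ok = (~h.same_chrom()) & (expected > 0)
        inter[ok] = h.raw[ok] / expected[ok]
    return replace(h, inter=inter)


@dataclass(frozen=True)
class SimilarityTable:
    """Symmetric nonnegative similarity for unordered pairs of adjacencies."""

    scores: Mapping  # frozenset({adj1, adj2}) -> float
    elements: tuple  # all adjacencies, in a fixed deterministic order

    def of(self, p: Adjacency, q: Adjacency) -> float:
        if p == q:
            raise KeyError("self-similarity is not defined")
        try:
            return self.scores[frozenset((p, q))]
        except KeyError:
            raise KeyError(f"no similarity for {sorted(p)}, {sorted(q)}") from None


def adjacency_similarity(
    a: Genome,
    regions: Mapping,
    h: HicDataset,
    mode: str = "normalized",
) -> SimilarityTable:
    """Similarity of every adjacency pair of A from Hi-C contacts.

    ``regions`` maps each adjacency to its breakpoint region
    ``(chrom, start, end)``; an adjacency is assigned the bin containing
    its region midpoint.  Same-chromosome pairs read INTRA (or raw),
    cross-chromosome pairs INTER (or raw).  Two adjacencies falling in the
    same bin use that bin's diagonal entry.
    """
    if mode not in ("raw", "normalized"):
        raise ValueError(f"mode must be 'raw' or 'normalized', got {mode!r}")
    if mode == "normalized":
        if h.intra is None:
            h = normalize_intra(h)
        if h.inter is None:
            h = normalize_inter(h)
    elements = tuple(sorted(a.adjacencies, key=sorted))
    bin_of = {}
    for adj in elements:
        try:
            chrom, start, end = regions[adj]
        except KeyError:
            raise GenomeError(f"adjacency {sorted(adj)} has no breakpoint region") from None
        bin_of[adj] = (chrom, h.bin_at(chrom, (start + end) // 2))
    scores = {}
    for i, p in enumerate(elements):
        for q in elements[i + 1 :]:
            (cp, bp), (cq, bq) = bin_of[p], bin_of[q]
            if mode == "raw":
                val = h.raw[bp, bq]
            elif cp == cq:
                val = h.intra[bp, bq]
            else:
                val = h.inter[bp, bq]
            scores[frozenset((p, q))] = 0.0 if np.isnan(val) else float(val)
    return SimilarityTable(scores, elements)


@dataclass(frozen=True)
class ColoringQuality:
    clustering_weight: float
    divergence: int


def clustering_weight(coloring: Coloring, sim: SimilarityTable) -> float:
    """Sum over clusters of the medoid's similarity to the rest of its cluster.

    The medoid of a cluster maximizes the sum of similarities to the other
    members; singletons contribute 0.
    """
    by_color: dict = {}
    for adj, color in coloring.items():
        by_color.setdefault(color, []).append(adj)
    total = 0.0
    for members in by_color.values():
        if len(members) < 2:
            continue
        total += max(
            sum(sim.of(m, other) for other in members if other != m) for m in members
        )
    return total


def kmedoids_coloring(
    sim: SimilarityTable, k: int, seed: int, max_iter: int = 100
) -> Coloring:
    """Weight-maximizing k-medoids clustering of the adjacencies.

    Starts from k random centroids, assigns each element to its most
    similar centroid, recomputes medoids, and stops when the clustering
    weight no longer increases (or after ``max_iter`` rounds).  Emptied
    clusters are reseeded with the element least similar to the current
    centroids.  Ties break toward the lowest element index, so runs are
    deterministic under a fixed seed.
    """
    elements = sim.elements
    n = len(elements)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    rng = np.random.default_rng(seed)
    pos = {adj: i for i, adj in enumerate(elements)}
    centroids = [elements[i] for i in sorted(rng.choice(n, size=k, replace=False))]

    def s(p, q):
        return 0.0 if p == q else sim.of(p, q)

    def assign(cents):
        clusters: list = [[] for _ in cents]
        for adj in elements:
            if adj in cents:
                clusters[cents.index(adj)].append(adj)
                continue
            best = max(
                range(len(cents)),
                key=lambda j: (s(adj, cents[j]), -j),
            )
            clusters[best].append(adj)
        for j, members in enumerate(clusters):
            if members:
                continue
            lonely = min(
                (adj for adj in elements if adj not in cents),
                key=lambda adj: (sum(s(adj, c) for c in cents), pos[adj]),
            )
            for other in clusters:
                if lonely in other:
                    other.remove(lonely)
            members.append(lonely)
            cents[j] = lonely
        return clusters

    def medoid(members):
        return max(members, key=lambda m: (sum(s(m, o) for o in members), -pos[m]))

    def weight(clusters):
        return sum(
            max(sum(s(m, o) for o in members) for m in members)
            for members in clusters
            if len(members) > 1
        )

    clusters = assign(centroids)
    best_w = weight(clusters)
    for _ in range(max_iter):
        centroids = [medoid(members) for members in clusters]
        new_clusters = assign(centroids)
        w = weight(new_clusters)
        if w <= best_w:
            break
        clusters, best_w = new_clusters, w
    return Coloring(
        {adj: j for j, members in enumerate(clusters) for adj in members},
        palette=range(k),
    )


# ---------------------------------------------------------------------------
# 1D structure: adjacency order, linear and random colorings, divergence
# ---------------------------------------------------------------------------


def adjacency_order(g: BlockGenome):
    """Per chromosome, the adjacencies in 1D order along the chromosome.

    For a linear chromosome with blocks b1..bm this is the left external,
    the m-1 internals, then the right external.  Circular chromosomes list
    their internals from the canonical block rotation.  Also returns the
    underlying adjacency-set genome.
    """
    genome, names = block_to_adjacency(g)
    index = genome.index()
    order = {name: i for i, name in enumerate(g.block_names, 1)}
    per_chrom = []
    for ch in g.chromosomes:
        exts = []
        for token in ch.blocks:
            name = token.lstrip("-")
            i = order[name]
            tail, head = 2 * i - 1, 2 * i
            exts.append((head, tail) if token.startswith("-") else (tail, head))
        adjs = []
        if not ch.circular:
            adjs.append(index[exts[0][0]])
        for (_, right), (left, _) in zip(exts, exts[1:]):
            adjs.append(index[right])
        adjs.append(index[exts[-1][1]])  # right external, or the closing adjacency
        per_chrom.append(adjs)
    return genome, per_chrom


def linear_coloring(g: BlockGenome, k: int, seed: int) -> Coloring:
    """Color adjacencies by contiguous chromosome segments.

    Chooses ``k - C`` cut blocks uniformly at random (C = chromosome count)
    and cuts each chromosome on the left side of its chosen blocks; every
    resulting segment holds at least one adjacency and gets its own color.
    Only defined for genomes whose chromosomes are all linear.
    """
    if any(ch.circular for ch in g.chromosomes):
        raise GenomeError("linear coloring requires linear chromosomes")
    genome, per_chrom = adjacency_order(g)
    c = len(g.chromosomes)
    n_adj = sum(len(adjs) for adjs in per_chrom)
    if not c <= k <= n_adj:
        raise ValueError(f"k={k} out of range {c}..{n_adj}")
    rng = np.random.default_rng(seed)
    blocks = list(g.block_names)
    picked = rng.choice(len(blocks), size=k - c, replace=False)
    cuts = {blocks[i] for i in picked.tolist()}
    assignment = {}
    color = 0
    for ch, adjs in zip(g.chromosomes, per_chrom):
        # adjacency j (0-based) sits on the left side of block j+1; cutting
        # inside block b therefore starts a new segment at the adjacency to
        # its right.  A chromosome with m blocks has m+1 adjacencies, so
        # every cut pattern leaves each segment with >= 1 adjacency.
        for j, adj in enumerate(adjs):
            if j > 0 and ch.blocks[j - 1].lstrip("-") in cuts:
                color += 1
            assignment[adj] = color
        color += 1
    # renumber colors densely 0..k-1
    relabel = {old: new for new, old in enumerate(sorted(set(assignment.values())))}
    coloring = Coloring({adj: relabel[c_] for adj, c_ in assignment.items()})
    if len(coloring.palette) != k:
        raise GenomeError("cut choice did not yield k segments")  # pragma: no cover
    return coloring


def random_coloring(g: Genome, k: int, seed: int) -> Coloring:
    """Uniform random surjective coloring: one random adjacency per color,
    the rest colored independently and uniformly."""
    elements = sorted(g.adjacencies, key=sorted)
    if not 1 <= k <= len(elements):
        raise ValueError(f"k={k} out of range 1..{len(elements)}")
    rng = np.random.default_rng(seed)
    assignment = {}
    forced = rng.choice(len(elements), size=k, replace=False)
    for color, i in enumerate(forced):
        assignment[elements[i]] = color
    for adj in elements:
        if adj not in assignment:
            assignment[adj] = int(rng.integers(k))
    return Coloring(assignment, palette=range(k))


def divergence_from_linearity(coloring: Coloring, g: BlockGenome) -> int:
    """Total gaps plus extra chromosome parts, summed over colors.

    For each color, its adjacencies are split by chromosome into l parts;
    each 1D discontinuity inside a part is a gap; the color contributes
    (gaps + l - 1).  Zero iff every color is one contiguous run on a single
    chromosome — in particular every linear coloring scores 0.
    """
    genome, per_chrom = adjacency_order(g)
    coloring.validate_total(genome)
    position = {}
    for ci, adjs in enumerate(per_chrom):
        for j, adj in enumerate(adjs):
            position[adj] = (ci, j)
    by_color: dict = {}
    for adj in genome.adjacencies:
        if adj not in position:
            raise GenomeError(f"adjacency {sorted(adj)} has no 1D position")
        by_color.setdefault(coloring.of(adj), []).append(position[adj])
    total = 0
    for positions in by_color.values():
        by_chrom: dict = {}
        for ci, j in positions:
            by_chrom.setdefault(ci, []).append(j)
        total += len(by_chrom) - 1
        for js in by_chrom.values():
            js.sort()
            total += sum(1 for a, b in zip(js, js[1:]) if b - a > 1)
    return total
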