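# mlsr — minimum local scenarios for DCJ genome rearrangement

Comparative genomics infers how one genome's gene order evolved into
another's through rearrangements (inversions, translocations, fusions,
fissions), all of which the **double cut and join (DCJ)** operation
captures uniformly.  Classical tools minimize scenario *length*; `mlsr`
instead minimizes how often a scenario does something *implausible*.

Given two genomes A and B over the same syntenic blocks, plus a coloring
`col : A → Δ` that partitions A's adjacencies into classes (typically 3D
chromatin neighborhoods inferred from Hi-C contact maps), a DCJ acting on
two adjacencies of one color is **local** (cost 0) and a DCJ acting across
colors is **non-local** (cost 1).  The **minimum local scenario (MLS)**
problem asks for a DCJ scenario from A to B, of any length, with the
fewest non-local moves.

The central result implemented here: build the **junction graph**
`J(A, B, col)` — vertices are the colors, one edge per internal adjacency
`{a, b}` of B joining the colors of the A-adjacencies containing `a` and
`b` — and the MLS cost is

```
w = e(J) − c(J)
```

where `e(J)` is the edge count and `c(J)` the size of a **maximum
edge-disjoint cycle packing (MECP)** of J.  Computing `c(J)` is NP-hard,
but it is exponential only in the number of colors: `mlsr` strips loops
and digons, enumerates the simple cycles of the small residual graph, and
solves the set-packing exactly.  It also provides the companion lower
bound `w ≥ (2/3)e − (1/3)c₂ − (2/3)c₁` and a 3/2-approximation from the
loop/digon packing alone.  Beyond the cost, `mlsr` reconstructs an
**explicit optimal scenario**: genomes are capped to circular form
realizing an Eulerian extension of J, each packed cycle is sorted by
2-breaks lifted to non-local DCJs, and the scenario is projected back to
the original genomes — every emitted scenario is replayed and verified.

Who this is for: researchers studying rearrangement scenarios under
spatial (Hi-C) or other positional constraints, and anyone needing a
tested reference implementation of weighted-DCJ machinery (adjacency
graphs, junction graphs, 2-break sorting, genome capping).

## Worked example

The single-chromosome genome `A B −C` (read: block C inverted) versus the
same chromosome with B also inverted.  In pair-coded form A =
{{1,2},{3,4},{5},{6}} and B = {{1,4},{2,3},{5},{6}}; adjacency {1,2} is
colored `y`, {3,4} `z`, and the telomeres `t` and `x`:

```
$ cat exA.adj            $ cat exB.adj
1 2 y                    1 4
3 4 z                    2 3
5 t                      5
6 x                      6

$ mlsr scenario exA.adj exB.adj
cost	1
junction_edges	2
packing_size	1
lower_bound	1
(1,2|y),(3,4|z) -> (1,4|y),(2,3|z) cost=1
```

The junction graph has two parallel `(y, z)` edges — one per internal
adjacency of B — and they pack into a single digon, so `w = 2 − 1 = 1`:
any transformation must pay exactly one non-local move, and the reported
scenario achieves it by cutting `{1,2}` and `{3,4}` and rejoining across
the two colors (the block inversion of B).

The tight case for the approximation is a triangle junction graph,
produced by the built-in reduction from MECP (`mlsr reduce`):

```
$ printf 'u v e1\nv w e2\nw u e3\n' > tri.edges
$ mlsr reduce tri.edges -o tri
$ mlsr cost tri.A tri.B          $ mlsr approx tri.A tri.B
cost	2                        cost	3
junction_edges	3                junction_edges	3
```

The triangle packs a single cycle, so the optimum is `w = e − c = 3 − 1 =
2`, while the greedy loop/digon packing finds nothing and guarantees only
3 — attaining the approximation ratio 3/2 exactly.

Hi-C-driven colorings are built with `mlsr color`: `hic-normalize`
applies the expected-at-distance (intra) and coverage-product (inter)
normalizations, `kmedoids` clusters adjacencies by contact similarity,
`linear` and `random` give the 1D-contiguous and uniform baselines, and
`evaluate` reports MLS cost, clustering weight and divergence from
linearity for any coloring.

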