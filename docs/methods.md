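# Methods

## Model

A genome is a set of adjacencies over block extremities: internal
adjacencies are unordered pairs, external adjacencies are singletons at
linear chromosome ends, and every extremity occurs exactly once.  A DCJ
move rewrites one or two adjacencies by one of four templates (pair–pair,
pair–telomere, split, join).  A coloring `col : A → Δ` makes a move local
(cost 0) when the consumed colors agree — for a split, when the freely
chosen color of the second product equals the consumed color — and
non-local (cost 1) otherwise.  When a move produces two adjacencies, which
product inherits which consumed color is itself a choice; `DcjMove`
records the branch explicitly rather than leaving it implicit, because
scenario replay must be exact.

The minimum local scenario (MLS) cost from A to B is `e(J) − c(J)` for
the junction graph `J(A, B, col)` (vertices Δ, one edge per internal
adjacency of B joining the colors of its two A-neighbors in the adjacency
graph), with `c(J)` the maximum number of edge-disjoint cycles.  The
implementation treats this identity as a theorem to be *checked*, not
assumed: every constructed scenario is replayed and its non-local count
compared against the formula, and the test suite confirms the formula
against an independent exhaustive search on small instances.

## Exact cycle packing

Loops are always packable and, for each pair of vertices with edge
multiplicity m, ⌊m/2⌋ digons can be packed without loss of optimality (an
exchange argument: two parallel edges used by two different cycles can be
rewired into a digon plus one combined cycle).  After removing those, the
residual graph is simple; its simple cycles are enumerated
(`networkx.simple_cycles`) under a configurable budget (default 10⁶,
exceeding it is an explicit error, never silent truncation) and a maximum
set packing over their edge sets is solved by depth-first branch and
bound with an include-first order, so the lexicographically smallest
optimum is returned deterministically.  The set-packing step sits behind
a single function so an integer-programming backend could be substituted;
the built-in exact search needs no solver dependency.  A brute-force
oracle (all edge subsets that are connected and 2-regular, then exhaustive
disjoint selection) validates the solver on every graph with ≤ 10 edges
used in tests, which also validates the ⌊m/2⌋ digon rule empirically.

## Scenario construction

1. **Pack and extend.**  Compute a packing of J; duplicate each uncovered
   edge.  For a maximum packing the uncovered set is acyclic (a cycle of
   uncovered edges would contradict maximality), so the duplicates form a
   forest; for the greedy packing they may contain cycles, which are
   peeled off first.  The extended graph J′ is Eulerian.
2. **Cap.**  Every external adjacency gets an artificial partner; the
   duplicated edges are realized as chains of telomeric pairs (closed
   chains for the peeled cycles, open chains for the forest paths, split
   at odd-degree vertices); finally all dangling chain ends and caps are
   closed pairwise *within each color*, so the new junction edges are all
   loops.  When a color holds an odd number of each kind of dangling end,
   one extra bridging extremity joins them.  The construction asserts that
   the capped junction graph agrees with J′ on all non-loop edges and that
   port counts pair up; violations are internal errors, not recoverable
   states.
3. **Sort.**  Each packed cycle of length l is terminalized with l − 1
   2-breaks, splitting off one loop at a time; each 2-break is realized
   as a single non-local DCJ that swaps one extremity between two
   differently colored A-side pairs at the cycle's current position.  Uncovered edges pair with their
   duplicates as digons and take one 2-break each.
4. **Finish locally.**  With a terminal junction graph every
   adjacency-graph component is monochromatic, so B's remaining pairs are
   assembled by zero-cost moves.
5. **Project.**  The capped scenario is replayed while a parallel
   original-level state is maintained: telomeric pairs vanish, a pair with
   one artificial extremity projects to the external adjacency of its
   real member, moves whose projection changes nothing are dropped, and
   produced colors follow the capped coloring whenever the rewrite
   template permits.  One subtlety required care: a swap between two
   pairs that both keep only artificial partners would recolor external
   adjacencies of the original genome with no projectable move, silently
   shifting cost into later moves.  Before any such swap the solver emits
   a zero-cost *pre-merge* (junction graph unchanged) that gives the swap
   a real stay-behind partner, making its projection structural.  The
   final guard — replay must reach B with exactly `e(J) − c(J)` non-local
   moves — would catch any case this scheme missed.

## The exhaustive oracle

The independent check of optimality collapses states connected by free
moves before searching.  Two facts make the quotient exact: a zero-cost
move never transfers an extremity between color classes, and within one
class every pairing of its extremities is reachable for free (split all
pairs keeping the class color, then rejoin arbitrarily).  A colored
genome is therefore equivalent, up to free moves, to its extremity→color
map, and a unit-cost move either transfers one extremity to another class
or exchanges two extremities between classes (with small feasibility
side-conditions derived from the move templates).  B is reached when the
map is constant on B's internal pairs.  A* over these maps with the
admissible, consistent heuristic ⌈violated B-pairs / 2⌉ returns the exact
optimum in milliseconds where the unquotiented search needs millions of
states; the two are cross-checked on very small instances in the suite.

## Hi-C colorings

Intra-chromosomal contacts are divided by the mean contact at the same
bin offset pooled over all chromosomes (offsets with no observations stay
undefined rather than zero); by construction the distance-wise mean of
the normalized matrix is 1.  Inter-chromosomal contacts are divided by
`interaction_i · interaction_j / interaction_all`, which is invariant
under a global rescaling of the raw matrix and boosts loci with few total
contacts.  Adjacencies map to bins by breakpoint-region midpoint — the
mapping rule is an interpretation, chosen as the simplest deterministic
one — and two adjacencies sharing a bin use that bin's diagonal entry
(overridable by editing the similarity table).

k-medoids maximizes the clustering weight, the sum over clusters of the
medoid's similarity to the rest of its cluster (medoid-to-rest, not
all-pairs).  Iteration stops when the weight no longer increases, with a
cap of 100 rounds; emptied clusters are reseeded with the element least
similar to the current centroids; all ties break toward the lowest
element index so a seed fully determines the run.  The linear coloring
cuts chromosomes inside `k − C` randomly chosen blocks; because a
chromosome with m blocks has m + 1 adjacencies, every cut pattern leaves
each segment nonempty, so no retry logic is needed.  Divergence from
linearity is, per color, the number of 1D gaps plus (chromosome parts −
1), summed over colors; it is 0 exactly when every color is one
contiguous run, and the linear coloring always scores 0.  Circular
chromosomes are ordered from their canonical rotation for this measure
(the natural use case — chromosome arms — is linear).

## Synthetic data

`random_genome_pair` scrambles an identity genome with uniformly random
legal DCJs (default study conditions in tests: up to 8 blocks, up to 3
linear chromosomes or one circular, up to 10 moves, colorings with 2–4
colors — small enough that the exhaustive oracle can confirm optimality
on the ≤ 10-extremity subset while still exercising capping, telomeres
and every move template).  `random_eulerian_multigraph` draws unions of
random closed walks, guaranteeing even degrees by construction.
`instance_from_eulerian_graph` follows an Eulerian tour (Hierholzer,
smallest-neighbor first) to produce a genome pair and coloring whose
junction graph reproduces the input graph exactly — verified on every
call — turning the NP-hardness reduction into a trusted instance factory.
`synthetic_hic` combines a power-law distance decay (10/√(1+d) within
chromosomes, flat 1 across), a +100 within-cluster boost for planted
labels, and symmetric additive noise.  It emulates the two features the
coloring pipeline consumes — decay and block structure — and nothing
else: no compartment checkerboards, no domain boundaries, no coverage
biases, so passing tests show the pipeline's correctness, not that
k-medoids would resolve real chromatin structure.

## Limitations

* MECP is NP-hard; the exact solver is practical when the *palette* is
  small (cycle count grows with colors, not blocks).  The enumeration cap
  makes failure explicit.
* Equal block sets only: no insertions, deletions or duplications.
* The (1, 1+α) generalized cost problem is not solved; only the bound
  `(d_MLPS − d_MLS)·α` on the length excess of an optimal scenario is
  provided, with `d_MLPS` supplied by the caller.
* The adjacency→bin midpoint rule and same-bin diagonal similarity are
  interpretations; real analyses should check sensitivity to both.
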