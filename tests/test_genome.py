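"""Genome representation, parsing, renaming, and colored DCJ moves."""

import pytest
from hypothesis import given, settings, strategies as st

from mlsr import (
    Coloring,
    DcjMove,
    Genome,
    GenomeError,
    apply_move,
    block_to_adjacency,
    chromosomes_from_adjacencies,
    co_rename,
    parse_block_genome,
    replay,
)
from mlsr.genome import adjacency as adj


class TestParsing:
    def test_single_linear_chromosome(self):
        g = parse_block_genome("1 2 3 $")
        assert len(g.chromosomes) == 1
        assert g.chromosomes[0].blocks == ("1", "2", "3")
        assert not g.chromosomes[0].circular

    def test_inverted_block_and_circular_marker(self):
        g = parse_block_genome("1 -2 3 $\n4 5 @ # trailing comment")
        assert g.chromosomes[0].blocks == ("1", "-2", "3")
        assert g.chromosomes[1].circular

    @pytest.mark.parametrize(
        "text",
        ["1 2 $\n1 3 $", "1 ? $", "$", "1 2"],
        ids=["duplicate-block", "unknown-token", "empty-chromosome", "no-terminator"],
    )
    def test_malformed_documents_rejected(self, text):
        with pytest.raises(GenomeError):
            parse_block_genome(text)


class TestBlockToAdjacency:
    def test_three_block_linear_chromosome(self):
        # A B -C: adjacencies {A_h,B_t}, {B_h,C_h}, telomeres A_t, C_t
        g, names = block_to_adjacency(parse_block_genome("A B -C $"))
        label = {v: k for k, v in names.items() if isinstance(v, str)}
        expected = {
            frozenset((label["A_h"], label["B_t"])),
            frozenset((label["B_h"], label["C_h"])),
            frozenset((label["A_t"],)),
            frozenset((label["C_t"],)),
        }
        assert g.adjacencies == expected
        assert g.n_internal == 2 and g.n_external == 2

    def test_smallest_circular_genome(self):
        g, _ = block_to_adjacency(parse_block_genome("1 @"))
        assert g.adjacencies == {frozenset((1, 2))}
        assert g.n_external == 0

    def test_identical_genomes_give_identical_adjacencies(self):
        g1, _ = block_to_adjacency(parse_block_genome("1 2 $\n3 @"))
        g2, _ = block_to_adjacency(parse_block_genome("3 @\n1 2 $"))
        assert g1.adjacencies == g2.adjacencies

    @pytest.mark.parametrize(
        "text", ["1 2 3 $", "1 -2 3 $\n-4 5 @", "7 @", "2 -1 $\n3 $"]
    )
    def test_round_trip_through_chromosomes(self, text):
        bg = parse_block_genome(text)
        g, names = block_to_adjacency(bg)
        back = chromosomes_from_adjacencies(g, names)
        g2, _ = block_to_adjacency(back)
        assert g2.adjacencies == g.adjacencies


class TestCoRename:
    def test_canonical_form_of_a(self):
        a, _ = block_to_adjacency(parse_block_genome("A B -C $"))
        b, _ = block_to_adjacency(parse_block_genome("A -B -C $"))
        a2, b2, mapping = co_rename(a, b)
        assert a2.adjacencies == {
            frozenset((1, 2)),
            frozenset((3, 4)),
            frozenset((5,)),
            frozenset((6,)),
        }
        # same bijection applied to B: B is A after inverting block B
        assert b2.extremities == a2.extremities
        assert b2.n_internal == 2
        inv = {v: k for k, v in mapping.items()}
        assert {frozenset(inv[x] for x in p) for p in b2.adjacencies} == b.adjacencies

    def test_identity(self):
        a = Genome([adj(7, 3), adj(5)])
        a2, b2, _ = co_rename(a, a)
        assert a2.adjacencies == b2.adjacencies == {adj(1, 2), adj(3)}

    def test_mismatched_universes_rejected(self):
        with pytest.raises(GenomeError):
            co_rename(Genome([adj(1)]), Genome([adj(2)]))


class TestGenomeInvariants:
    def test_extremity_reuse_rejected(self):
        with pytest.raises(GenomeError):
            Genome([adj(1, 2), adj(2, 3)])

    def test_adjacency_size_bounds(self):
        with pytest.raises(GenomeError):
            Genome([frozenset((1, 2, 3))])


class TestMoves:
    def test_example1_move_costs_one_and_reaches_b(self, example1):
        a, b, col = example1
        mv = DcjMove(
            consumed=((adj(1, 2), "y"), (adj(3, 4), "z")),
            produced=((adj(1, 4), "y"), (adj(3, 2), "z")),
        )
        g2, c2, cost = apply_move(a, col, mv)
        assert cost == 1
        assert g2.adjacencies == b.adjacencies
        assert c2.of(adj(1, 4)) == "y" and c2.of(adj(3, 2)) == "z"

    def test_same_colored_pair_pair_is_local(self):
        g = Genome([adj(1, 2), adj(3, 4)])
        col = Coloring({adj(1, 2): "x", adj(3, 4): "x"})
        mv = DcjMove(
            consumed=((adj(1, 2), "x"), (adj(3, 4), "x")),
            produced=((adj(1, 3), "x"), (adj(2, 4), "x")),
        )
        _, _, cost = apply_move(g, col, mv)
        assert cost == 0

    def test_split_cost_depends_on_new_color(self):
        free = DcjMove(
            consumed=((adj(1, 2), "x"),),
            produced=((adj(1), "x"), (adj(2), "x")),
        )
        paid = DcjMove(
            consumed=((adj(1, 2), "x"),),
            produced=((adj(1), "x"), (adj(2), "z")),
        )
        assert free.cost == 0 and paid.cost == 1

    def test_consumed_adjacency_must_exist_with_matching_color(self, example1):
        a, _, col = example1
        missing = DcjMove(
            consumed=((adj(1, 3), "y"), (adj(2, 4), "z")),
            produced=((adj(1, 2), "y"), (adj(3, 4), "z")),
        )
        with pytest.raises(GenomeError):
            apply_move(a, col, missing)
        wrong_color = DcjMove(
            consumed=((adj(1, 2), "z"), (adj(3, 4), "y")),
            produced=((adj(1, 4), "z"), (adj(3, 2), "y")),
        )
        with pytest.raises(GenomeError):
            apply_move(a, col, wrong_color)

    def test_invalid_rewrites_rejected(self):
        with pytest.raises(GenomeError):
            DcjMove(  # extremities not conserved
                consumed=((adj(1, 2), "x"), (adj(3, 4), "x")),
                produced=((adj(1, 5), "x"), (adj(3, 2), "x")),
            )
        with pytest.raises(GenomeError):
            DcjMove(  # both extremities of one consumed pair kept together
                consumed=((adj(1, 2), "x"), (adj(3, 4), "y")),
                produced=((adj(1, 2), "x"), (adj(3, 4), "y")),
            )


class TestReplay:
    def test_empty_scenario_is_identity(self, example1):
        a, _, col = example1
        rr = replay(a, col, ())
        assert rr.genome.adjacencies == a.adjacencies and rr.total_cost == 0

    def test_example1_scenario(self, example1):
        a, b, col = example1
        mv = DcjMove(
            consumed=((adj(1, 2), "y"), (adj(3, 4), "z")),
            produced=((adj(1, 4), "y"), (adj(3, 2), "z")),
        )
        rr = replay(a, col, (mv,))
        assert rr.genome.adjacencies == b.adjacencies
        assert (rr.total_cost, rr.n_nonlocal, rr.n_local) == (1, 1, 0)

    def test_all_local_scenario_costs_zero(self):
        g = Genome([adj(1, 2), adj(3, 4)])
        col = Coloring({adj(1, 2): "x", adj(3, 4): "x"})
        s = (
            DcjMove(
                consumed=((adj(1, 2), "x"), (adj(3, 4), "x")),
                produced=((adj(1, 3), "x"), (adj(2, 4), "x")),
            ),
            DcjMove(
                consumed=((adj(1, 3), "x"), (adj(2, 4), "x")),
                produced=((adj(1, 2), "x"), (adj(3, 4), "x")),
            ),
        )
        rr = replay(g, col, s)
        assert rr.total_cost == 0 and rr.n_local == 2

    def test_inapplicable_move_reports_step(self, example1):
        a, b, col = example1
        mv = DcjMove(
            consumed=((adj(1, 2), "y"), (adj(3, 4), "z")),
            produced=((adj(1, 4), "y"), (adj(3, 2), "z")),
        )
        with pytest.raises(GenomeError, match="step 1"):
            replay(a, col, (mv, mv))


@st.composite
def colored_genomes(draw):
    n_pairs = draw(st.integers(1, 3))
    n_tel = draw(st.sampled_from([0, 2]))
    labels = list(range(1, 2 * n_pairs + n_tel + 1))
    perm = draw(st.permutations(labels))
    adjs = [frozenset(perm[2 * i : 2 * i + 2]) for i in range(n_pairs)]
    adjs += [frozenset((x,)) for x in perm[2 * n_pairs :]]
    colors = draw(st.lists(st.sampled_from("ab"), min_size=len(adjs), max_size=len(adjs)))
    return Genome(adjs), Coloring(dict(zip(adjs, colors)), palette="ab")


@settings(derandomize=True, max_examples=60)
@given(colored_genomes(), st.integers(0, 2**20))
def test_random_walks_conserve_extremities(gc, seed):
    """Every legal colored DCJ keeps the extremity multiset and leaves a
    valid genome (each extremity in exactly one adjacency)."""
    import random

    from mlsr.generators import _raw_successors

    genome, col = gc
    rnd = random.Random(seed)
    universe = sorted(genome.extremities)
    state = frozenset(col.items())
    for _ in range(4):
        succ = sorted(_raw_successors(state, ("a", "b")), key=repr)
        state, _cost = rnd.choice(succ)
        assert sorted(x for adj_, _ in state for x in adj_) == universe
        Genome([adj_ for adj_, _ in state])  # validates exactly-once coverage
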