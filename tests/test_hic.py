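"""Hi-C normalization, similarity, clustering, and linearity measures."""

from dataclasses import replace
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from mlsr import (
    Coloring,
    Genome,
    HicDataset,
    SimilarityTable,
    adjacency_similarity,
    clustering_weight,
    divergence_from_linearity,
    kmedoids_coloring,
    linear_coloring,
    normalize_inter,
    normalize_intra,
    parse_block_genome,
    random_coloring,
    synthetic_hic,
)
from mlsr.genome import GenomeError
from mlsr.genome import adjacency as adj
from mlsr.hic import adjacency_order


def single_chrom_dataset(raw):
    n = len(raw)
    bins = pd.DataFrame(
        {"chrom": ["c1"] * n, "start": range(0, 10 * n, 10), "end": range(10, 10 * n + 10, 10)}
    )
    return HicDataset(bins, np.asarray(raw, dtype=float))


class TestIntraNormalization:
    def test_constant_matrix_becomes_one(self):
        h = normalize_intra(single_chrom_dataset(np.full((4, 4), 7.0)))
        assert np.allclose(h.intra, 1.0)

    def test_three_bin_worked_example(self):
        # off-diagonals 4 at distance 1 and 2 at distance 2: both normalize to 1
        h = normalize_intra(single_chrom_dataset([[1, 4, 2], [4, 1, 4], [2, 4, 1]]))
        assert np.allclose(h.intra[0, 1], 1) and np.allclose(h.intra[0, 2], 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_distance_wise_mean_is_one(self, seed):
        ds, _ = synthetic_hic(2, 7, 3, noise=0.4, seed=seed)
        h = normalize_intra(ds)
        same = h.same_chrom()
        pos = np.arange(h.n_bins)
        dist = np.abs(pos[:, None] - pos[None, :])
        for d in range(7):
            mask = same & (dist == d)
            vals = h.intra[mask]
            vals = vals[~np.isnan(vals)]
            if len(vals):
                assert abs(vals.mean() - 1.0) < 1e-9

    def test_empty_dataset_rejected(self):
        empty = HicDataset(
            pd.DataFrame({"chrom": [], "start": [], "end": []}), np.zeros((0, 0))
        )
        with pytest.raises(ValueError):
            normalize_intra(empty)


class TestInterNormalization:
    def test_symmetry(self):
        ds, _ = synthetic_hic(2, 5, 2, noise=0.3, seed=1)
        h = normalize_inter(ds)
        m = ~np.isnan(h.inter)
        assert np.allclose(h.inter[m], h.inter.T[m])

    def test_global_rescaling_invariance(self):
        ds, _ = synthetic_hic(3, 4, 2, noise=0.2, seed=2)
        h1 = normalize_inter(ds)
        h2 = normalize_inter(replace(ds, raw=ds.raw * 3.7))
        m = ~np.isnan(h1.inter)
        assert np.allclose(h1.inter[m], h2.inter[m])

    def test_two_locus_hand_expansion(self):
        bins = pd.DataFrame(
            {"chrom": ["c1", "c2"], "start": [0, 0], "end": [10, 10]}
        )
        raw = np.array([[2.0, 3.0], [3.0, 5.0]])
        h = normalize_inter(HicDataset(bins, raw))
        total = raw.sum()
        expected = 3.0 / ((2 + 3) * (3 + 5) / total)
        assert np.isclose(h.inter[0, 1], expected)
        assert np.isnan(h.inter[0, 0])


class TestSimilarity:
    @pytest.fixture
    def toy(self):
        ds, _ = synthetic_hic(2, 3, 1, noise=0.0, seed=0)
        genome = Genome([adj(2 * i + 1, 2 * i + 2) for i in range(6)])
        elements = sorted(genome.adjacencies, key=sorted)
        regions = {
            e: (
                ds.bins.iloc[i]["chrom"],
                int(ds.bins.iloc[i]["start"]),
                int(ds.bins.iloc[i]["end"]),
            )
            for i, e in enumerate(elements)
        }
        return ds, genome, regions, elements

    def test_raw_mode_matches_matrix_lookup(self, toy):
        ds, genome, regions, elements = toy
        sim = adjacency_similarity(genome, regions, ds, mode="raw")
        for i, p in enumerate(elements):
            for j, q in enumerate(elements):
                if i < j:
                    assert sim.of(p, q) == pytest.approx(ds.raw[i, j])

    def test_normalized_mode_uses_intra_and_inter(self, toy):
        ds, genome, regions, elements = toy
        full = normalize_inter(normalize_intra(ds))
        sim = adjacency_similarity(genome, regions, ds, mode="normalized")
        assert sim.of(elements[0], elements[1]) == pytest.approx(full.intra[0, 1])
        assert sim.of(elements[0], elements[4]) == pytest.approx(full.inter[0, 4])

    def test_region_outside_bins_rejected(self, toy):
        ds, genome, regions, elements = toy
        bad = dict(regions)
        bad[elements[0]] = ("c1", 10**9, 10**9 + 10)
        with pytest.raises(ValueError):
            adjacency_similarity(genome, bad, ds, mode="raw")


class TestKMedoids:
    def make_sim(self, matrix):
        n = len(matrix)
        elements = tuple(adj(2 * i + 1, 2 * i + 2) for i in range(n))
        scores = {
            frozenset((elements[i], elements[j])): float(matrix[i][j])
            for i in range(n)
            for j in range(i + 1, n)
        }
        return SimilarityTable(scores, elements)

    def test_singletons_have_zero_weight(self):
        sim = self.make_sim(np.ones((4, 4)))
        col = kmedoids_coloring(sim, 4, seed=0)
        assert clustering_weight(col, sim) == 0
        assert len(set(col.assignment.values())) == 4

    def test_planted_blocks_recovered(self):
        block = np.kron(np.eye(2), np.full((3, 3), 10.0)) + 0.1
        sim = self.make_sim(block)
        best = max(
            (kmedoids_coloring(sim, 2, seed=s) for s in range(20)),
            key=lambda c: clustering_weight(c, sim),
        )
        groups = {}
        for a_, c_ in best.items():
            groups.setdefault(c_, set()).add(a_)
        assert sorted(len(g) for g in groups.values()) == [3, 3]
        assert {frozenset(sim.elements[:3]), frozenset(sim.elements[3:])} == {
            frozenset(g) for g in groups.values()
        }

    def test_deterministic_under_seed_and_k_range(self):
        sim = self.make_sim(np.arange(25).reshape(5, 5))
        c1 = kmedoids_coloring(sim, 2, seed=3)
        c2 = kmedoids_coloring(sim, 2, seed=3)
        assert c1 == c2
        with pytest.raises(ValueError):
            kmedoids_coloring(sim, 6, seed=0)


class TestClusteringWeight:
    def test_pair_cluster_weight_is_similarity(self):
        a1, a2 = adj(1, 2), adj(3, 4)
        sim = SimilarityTable({frozenset((a1, a2)): 2.5}, (a1, a2))
        assert clustering_weight(Coloring({a1: 0, a2: 0}), sim) == 2.5
        assert clustering_weight(Coloring({a1: 0, a2: 1}), sim) == 0

    def test_three_element_cluster_uses_medoid_sum(self):
        a1, a2, a3 = adj(1, 2), adj(3, 4), adj(5, 6)
        sim = SimilarityTable(
            {
                frozenset((a1, a2)): 1.0,
                frozenset((a1, a3)): 2.0,
                frozenset((a2, a3)): 4.0,
            },
            (a1, a2, a3),
        )
        # medoid is a3 with sum 2 + 4 = 6
        assert clustering_weight(Coloring({a1: 0, a2: 0, a3: 0}), sim) == 6.0


class TestLinearColoring:
    @pytest.fixture
    def genome(self):
        return parse_block_genome("1 2 3 $\n4 5 $")

    def test_one_color_per_chromosome(self, genome):
        col = linear_coloring(genome, 2, seed=0)
        _, per_chrom = adjacency_order(genome)
        for adjs in per_chrom:
            assert len({col.of(a_) for a_ in adjs}) == 1

    @pytest.mark.parametrize("k", range(2, 8))
    @pytest.mark.parametrize("seed", range(4))
    def test_divergence_is_always_zero(self, genome, k, seed):
        col = linear_coloring(genome, k, seed)
        assert len(col.palette) == k
        assert divergence_from_linearity(col, genome) == 0

    def test_maximal_cutting_gives_singletons(self, genome):
        col = linear_coloring(genome, 7, seed=1)
        assert len(set(col.assignment.values())) == 7

    def test_bounds_and_circular_rejected(self, genome):
        with pytest.raises(ValueError):
            linear_coloring(genome, 1, seed=0)
        with pytest.raises(ValueError):
            linear_coloring(genome, 8, seed=0)
        with pytest.raises(GenomeError):
            linear_coloring(parse_block_genome("1 2 @"), 1, seed=0)


class TestRandomColoring:
    def test_monochromatic_when_k_is_one(self):
        g = Genome([adj(1, 2), adj(3, 4), adj(5)])
        col = random_coloring(g, 1, seed=0)
        assert set(col.assignment.values()) == {0}

    @pytest.mark.parametrize("seed", range(50))
    def test_always_surjective(self, seed):
        g = Genome([adj(1, 2), adj(3, 4), adj(5), adj(6)])
        assert random_coloring(g, 3, seed).is_surjective()

    def test_frequencies_uniform(self):
        """Chi-square on pooled color counts over many seeded draws."""
        from scipy import stats  # noqa: PLC0415

        g = Genome([frozenset((2 * i + 1, 2 * i + 2)) for i in range(8)])
        k = 4
        counts = np.zeros(k)
        n_draws = 2000
        for s in range(n_draws):
            col = random_coloring(g, k, seed=s)
            for c in col.assignment.values():
                counts[c] += 1
        _, p = stats.chisquare(counts)
        assert p > 1e-4

    def test_k_bounds(self):
        g = Genome([adj(1, 2)])
        with pytest.raises(ValueError):
            random_coloring(g, 2, seed=0)


class TestDivergence:
    @pytest.fixture
    def genome(self):
        return parse_block_genome("1 2 3 $\n4 5 $")

    def test_color_spanning_two_chromosomes(self, genome):
        _, per_chrom = adjacency_order(genome)
        col = Coloring({a_: 0 for adjs in per_chrom for a_ in adjs})
        assert divergence_from_linearity(col, genome) == 1  # 0 gaps, l=2

    def test_single_gap(self, genome):
        _, per_chrom = adjacency_order(genome)
        first = per_chrom[0]
        assignment = {a_: 0 for a_ in first}
        assignment[first[1]] = 1  # positions 0 and 2 keep color 0
        assignment.update({a_: 2 for a_ in per_chrom[1]})
        assert divergence_from_linearity(Coloring(assignment), genome) == 1

    def test_zero_iff_contiguous_single_chromosome_runs(self, genome):
        _, per_chrom = adjacency_order(genome)
        contiguous = {a_: ci for ci, adjs in enumerate(per_chrom) for a_ in adjs}
        assert divergence_from_linearity(Coloring(contiguous), genome) == 0
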