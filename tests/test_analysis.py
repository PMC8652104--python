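"""Hollow-area detection against an exhaustive oracle, and genome sorting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panpav import (
    PavModelError,
    find_hollow_areas,
    hollow_areas_to_bed,
    read_annotations,
    sort_genomes_by_gene_list,
    sort_genomes_by_region,
    sort_genomes_by_tree,
)
from panpav.analysis import SortMode
from panpav.fixtures import FixtureSpec, generate_gff3, generate_matrix

from conftest import brute_force_hollow_areas, matrix_from_absent_sets, random_small_matrix


def as_tuples(areas):
    return {
        (h.panchromosome, h.first_block_index, h.last_block_index, h.absent_genomes)
        for h in areas
    }


class TestHollowAreas:
    def test_toy_L2_g1(self, toy_matrix):
        areas = find_hollow_areas(toy_matrix, min_blocks=2, min_genomes=1)
        assert as_tuples(areas) == {("chr1", 1, 3, frozenset({"B"}))}

    def test_toy_L2_g2(self, toy_matrix):
        areas = find_hollow_areas(toy_matrix, min_blocks=2, min_genomes=2)
        assert as_tuples(areas) == {("chr1", 1, 2, frozenset({"B", "C"}))}

    def test_no_absence_no_hollow(self):
        m = matrix_from_absent_sets(["a", "b"], [set()] * 5)
        for L, g in [(1, 1), (2, 1), (1, 2)]:
            assert find_hollow_areas(m, L, g) == []

    def test_overlapping_maximal_intervals_both_reported(self):
        # b1:{X,Y} b2:{X} b3:{X,Y}: [0,2]x{X} and [0,0],[2,2]x{X,Y} all maximal
        m = matrix_from_absent_sets(["W", "X", "Y"], [{"X", "Y"}, {"X"}, {"X", "Y"}])
        assert as_tuples(find_hollow_areas(m, 1, 2)) == {
            ("chr1", 0, 0, frozenset({"X", "Y"})),
            ("chr1", 2, 2, frozenset({"X", "Y"})),
        }
        assert as_tuples(find_hollow_areas(m, 1, 1)) == {
            ("chr1", 0, 2, frozenset({"X"})),
        }

    def test_parameter_validation(self, toy_matrix):
        with pytest.raises(PavModelError):
            find_hollow_areas(toy_matrix, min_blocks=0, min_genomes=1)
        with pytest.raises(PavModelError):
            find_hollow_areas(toy_matrix, min_blocks=1, min_genomes=4)

    def test_span_bp_sums_block_widths(self, toy_matrix):
        (h,) = find_hollow_areas(toy_matrix, 2, 2)
        assert h.n_blocks == 2 and h.span_bp == 20  # two 10-bp blocks

    @pytest.mark.parametrize("seed", range(40))
    def test_equals_exhaustive_enumeration(self, seed):
        """Sliding-window finder vs brute-force interval enumeration."""
        rng = np.random.default_rng(seed)
        m = random_small_matrix(rng)
        L = int(rng.integers(1, 4))
        g = int(rng.integers(1, m.n_genomes + 1))
        expected = brute_force_hollow_areas(m, L, g)
        assert as_tuples(find_hollow_areas(m, L, g)) == expected

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_maximality_and_membership_hold_directly(self, seed):
        """Every reported area satisfies its own definition on the matrix."""
        rng = np.random.default_rng(seed)
        m = random_small_matrix(rng, max_genomes=6, max_blocks=25)
        g = int(rng.integers(1, m.n_genomes + 1))
        for h in find_hollow_areas(m, 1, g):
            blist = m.blocks[h.panchromosome]
            ids = [b.block_id for b in blist[h.first_block_index : h.last_block_index + 1]]
            absent = (m.counts.loc[ids] == 0).all(axis=0)
            inter = frozenset(absent.index[absent])
            assert inter == h.absent_genomes and len(inter) >= g
            for k in (h.first_block_index - 1, h.last_block_index + 1):
                if 0 <= k < len(blist):
                    wider = ids + [blist[k].block_id]
                    wider_inter = (m.counts.loc[wider] == 0).all(axis=0).sum()
                    assert wider_inter < g  # extension breaks the threshold

    def test_planted_hollow_recovered_exactly(self):
        spec = FixtureSpec(
            n_genomes=6, n_blocks=40, seed=3,
            planted_hollows=(("chr1", 10, 10, ("g2", "g3")),),
        )
        m = generate_matrix(spec)
        areas = find_hollow_areas(m, min_blocks=10, min_genomes=2)
        assert as_tuples(areas) == {("chr1", 10, 19, frozenset({"g2", "g3"}))}

    def test_bed_export(self, toy_matrix):
        areas = find_hollow_areas(toy_matrix, 2, 2)
        assert hollow_areas_to_bed(toy_matrix, areas) == "chr1\t10\t30\tB,C\n"
        assert hollow_areas_to_bed(toy_matrix, []) == ""


class TestSortByTree:
    def test_tree_order(self, toy_matrix):
        o = sort_genomes_by_tree(toy_matrix, ["C", "A", "B"])
        assert o.order == ("C", "A", "B") and o.mode is SortMode.TREE

    def test_missing_genome_appended_in_matrix_order(self, toy_matrix):
        assert sort_genomes_by_tree(toy_matrix, ["C", "A"]).order == ("C", "A", "B")

    def test_extra_leaf_ignored(self, toy_matrix):
        assert sort_genomes_by_tree(toy_matrix, ["C", "X", "A", "B"]).order == ("C", "A", "B")


class TestSortByRegion:
    def test_pivot_A_hand_computed(self, toy_matrix):
        o = sort_genomes_by_region(toy_matrix, "chr1", (1, 3), "A")
        assert o.order == ("A", "C", "B")
        assert o.keys == (0.0, 2.0, 3.0)

    def test_pivot_B_hand_computed(self, toy_matrix):
        o = sort_genomes_by_region(toy_matrix, "chr1", (1, 3), "B")
        assert o.order == ("B", "C", "A")
        assert o.keys == (0.0, 1.0, 3.0)

    def test_identical_region_preserves_matrix_order(self, toy_matrix):
        o = sort_genomes_by_region(toy_matrix, "chr1", (0, 0), "B")  # block 0 all present
        assert o.order == ("A", "B", "C") and set(o.keys) == {0.0}

    def test_pivot_always_first_with_zero_key(self):
        rng = np.random.default_rng(99)
        m = random_small_matrix(rng)
        chrom = m.panchromosomes[0]
        for pivot in m.genomes:
            o = sort_genomes_by_region(m, chrom, (0, len(m.blocks[chrom]) - 1), pivot)
            assert o.order[0] == pivot and o.keys[0] == 0.0
            assert sorted(o.order) == sorted(m.genomes)
            assert list(o.keys) == sorted(o.keys)

    def test_errors(self, toy_matrix):
        with pytest.raises(PavModelError):
            sort_genomes_by_region(toy_matrix, "chr1", (1, 3), "Z")
        with pytest.raises(PavModelError):
            sort_genomes_by_region(toy_matrix, "chrX", (1, 3), "A")
        with pytest.raises(PavModelError):
            sort_genomes_by_region(toy_matrix, "chr1", (3, 1), "A")

    def test_idempotent_resort(self, toy_matrix):
        o1 = sort_genomes_by_region(toy_matrix, "chr1", (1, 3), "A")
        o2 = sort_genomes_by_region(toy_matrix, "chr1", (1, 3), "A")
        assert o1 == o2


class TestSortByGeneList:
    @pytest.fixture
    def matrix_and_cards(self):
        m = generate_matrix(FixtureSpec(n_genomes=5, n_blocks=30, seed=13))
        cards = read_annotations(generate_gff3(m, n_genes=8, seed=13), m)
        return m, cards

    def test_single_core_gene_keeps_matrix_order(self, toy_matrix):
        gff = "##gff-version 3\nchr1\tsrc\tgene\t1\t10\t.\t+\t.\tID=geneK\n"  # block 0
        cards = read_annotations(gff, toy_matrix)
        o = sort_genomes_by_gene_list(toy_matrix, cards, ["geneK"])
        assert o.order == ("A", "B", "C") and set(o.keys) == {1.0}

    def test_genome_missing_all_genes_sorts_last(self, toy_matrix):
        gff = (
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t11\t20\t.\t+\t.\tID=gene2\n"   # block 1: absent B,C
            "chr1\tsrc\tgene\t31\t40\t.\t+\t.\tID=gene4\n"   # block 3: absent B
        )
        cards = read_annotations(gff, toy_matrix)
        o = sort_genomes_by_gene_list(toy_matrix, cards, ["gene2", "gene4"])
        assert o.order[-1] == "B" and o.keys[-1] == 0.0
        assert o.order == ("A", "C", "B") and o.keys == (2.0, 1.0, 0.0)

    def test_matches_brute_force_recount(self, matrix_and_cards):
        m, cards = matrix_and_cards
        gene_ids = [c.gene_id for c in cards[:3]]
        o = sort_genomes_by_gene_list(m, cards, gene_ids)
        # independent recount
        keys = {}
        for gname in m.genomes:
            n_ok = 0
            for gid in gene_ids:
                card = next(c for c in cards if c.gene_id == gid)
                sel = [
                    b.block_id for b in m.blocks[card.panchromosome]
                    if b.start < card.stop and card.start < b.stop
                ]
                if all(int(m.counts.at[s, gname]) >= 1 for s in sel):
                    n_ok += 1
            keys[gname] = n_ok
        expected = sorted(m.genomes, key=lambda g: (-keys[g], m.genomes.index(g)))
        assert list(o.order) == expected
        assert [int(k) for k in o.keys] == [keys[g] for g in o.order]

    def test_unresolvable_gene_raises_with_name(self, matrix_and_cards):
        m, cards = matrix_and_cards
        with pytest.raises(PavModelError, match="nope"):
            sort_genomes_by_gene_list(m, cards, ["nope"])
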