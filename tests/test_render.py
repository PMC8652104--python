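"""Beeswarm layout, overview binning and SVG rendering geometry."""

import re
import xml.etree.ElementTree as ET

import numpy as np
import pytest

from panpav import (
    PavModelError,
    ViewConfig,
    layout_beeswarm,
    overview_bins,
    read_annotations,
    render_overview,
    render_view,
)
from panpav.fixtures import FixtureSpec, generate_gff3, generate_matrix

from conftest import matrix_from_absent_sets

SVG_NS = "{http://www.w3.org/2000/svg}"


def cells(svg_text):
    root = ET.fromstring(svg_text)
    return [e for e in root.iter(f"{SVG_NS}rect") if e.get("class") == "cell"]


class TestBeeswarm:
    def test_disjoint_marks_share_lane_zero(self):
        p = layout_beeswarm([("a", 0, 2), ("b", 10, 2), ("c", 20, 2)])
        assert [x.lane for x in p] == [0, 0, 0]

    def test_mutually_overlapping_marks_stack(self):
        p = layout_beeswarm([("a", 0, 10), ("b", 1, 10), ("c", 2, 10)])
        assert [x.lane for x in p] == [0, 1, 2]

    def test_chain_reuses_lane_zero(self):
        # a-b overlap, b-c overlap, a-c disjoint -> lanes [0, 1, 0]
        p = layout_beeswarm([("a", 0, 4), ("b", 3, 4), ("c", 6, 4)])
        assert [(x.feature_id, x.lane) for x in p] == [("a", 0), ("b", 1), ("c", 0)]

    def test_ties_broken_by_id(self):
        p = layout_beeswarm([("z", 5, 4), ("a", 5, 4)])
        assert [x.feature_id for x in p] == ["a", "z"]

    def test_nonpositive_width_raises(self):
        with pytest.raises(PavModelError):
            layout_beeswarm([("a", 0, 0)])

    @pytest.mark.parametrize("seed", range(10))
    def test_no_overlap_within_a_lane(self, seed):
        rng = np.random.default_rng(seed)
        marks = [
            (f"f{i}", float(rng.uniform(0, 200)), float(rng.uniform(1, 30)))
            for i in range(40)
        ]
        placements = layout_beeswarm(marks)
        by_lane = {}
        for p in placements:
            by_lane.setdefault(p.lane, []).append(p)
        for lane_marks in by_lane.values():
            lane_marks.sort(key=lambda p: p.x_min)
            for a, b in zip(lane_marks, lane_marks[1:]):
                assert a.x_max <= b.x_min


class TestOverviewBins:
    def test_all_present_maximal_everywhere(self):
        m = matrix_from_absent_sets(["a", "b"], [set()] * 8)
        assert np.allclose(overview_bins(m, "chr1", 16), 1.0)

    def test_single_bin_is_matrix_wide_mean(self):
        m = matrix_from_absent_sets(["a", "b"], [set(), {"a"}, {"a", "b"} - {"b"}, {"b"}])
        expected = np.mean([(m.counts.loc[b.block_id] >= 1).mean() for b in m.iter_blocks()])
        assert overview_bins(m, "chr1", 1)[0] == pytest.approx(expected)

    def test_matches_brute_force_per_bin_recount(self):
        m = generate_matrix(FixtureSpec(n_genomes=6, n_blocks=30, seed=17))
        width_px = 13
        got = overview_bins(m, "chr1", width_px)
        blist = m.blocks["chr1"]
        lo, hi = m.extent("chr1")
        edges = np.linspace(lo, hi, width_px + 1)
        for k in range(width_px):
            fr = [
                (m.counts.loc[b.block_id] >= 1).mean()
                for b in blist
                if b.start < edges[k + 1] and edges[k] < b.stop
            ]
            assert got[k] == pytest.approx(np.mean(fr) if fr else 0.0)

    def test_unknown_panchromosome_raises(self, toy_matrix):
        with pytest.raises(PavModelError):
            overview_bins(toy_matrix, "chrX", 10)

    def test_overview_fragment_one_rect_per_bin(self, toy_matrix):
        frag = render_overview(toy_matrix, "chr1", 25)
        assert frag.count("overview-bin") == 25


class TestRenderView:
    def config(self, **kw):
        defaults = dict(
            panchromosome="chr1", show_overview=False, show_annotations=False,
            show_coordinates=False, show_repeats=False,
        )
        defaults.update(kw)
        return ViewConfig(**defaults)

    def test_cell_count_is_blocks_times_genomes(self):
        m = matrix_from_absent_sets(["a", "b"], [set(), {"a"}, set()])
        svg = render_view(m, None, self.config())
        assert len(cells(svg)) == 6

    def test_cells_carry_stable_identifiers_and_colors(self, toy_matrix):
        svg = render_view(toy_matrix, None, self.config(threshold=0.95))
        by_key = {(c.get("data-genome"), c.get("data-block")): c for c in cells(svg)}
        assert len(by_key) == 18
        # block b1 present everywhere -> CORE -> orange fill for present cells
        assert by_key[("A", "b1")].get("fill") == "#E69F00"
        # block b2 absent in B -> absent color; present in A -> variable blue
        assert by_key[("B", "b2")].get("fill") == "#E8E8E8"
        assert by_key[("A", "b2")].get("fill") == "#56B4E9"

    def test_fully_present_matrix_all_core_marks_orange(self):
        m = matrix_from_absent_sets(["a", "b", "c"], [set()] * 4)
        svg = render_view(m, None, self.config(threshold=0.95))
        root = ET.fromstring(svg)
        marks = [e for e in root.iter(f"{SVG_NS}rect") if e.get("class") == "status"]
        assert len(marks) == 4
        assert all(e.get("fill") == "#E69F00" for e in marks)

    def test_byte_identical_across_runs(self):
        spec = FixtureSpec(n_genomes=4, n_blocks=25, seed=8)
        m1, m2 = generate_matrix(spec), generate_matrix(spec)
        cards1 = read_annotations(generate_gff3(m1, 6, seed=8), m1)
        cards2 = read_annotations(generate_gff3(m2, 6, seed=8), m2)
        cfg = ViewConfig(panchromosome="chr1")
        assert render_view(m1, cards1, cfg) == render_view(m2, cards2, cfg)

    def test_zoom_rescales_x_linearly(self, toy_matrix):
        svg1 = render_view(toy_matrix, None, self.config(px_per_bp=1.0))
        svg2 = render_view(toy_matrix, None, self.config(px_per_bp=2.0))
        w1 = {c.get("data-block"): float(c.get("width")) for c in cells(svg1)}
        w2 = {c.get("data-block"): float(c.get("width")) for c in cells(svg2)}
        assert all(w2[b] == pytest.approx(2 * w1[b]) for b in w1)
        h1 = {c.get("data-block"): float(c.get("height")) for c in cells(svg1)}
        h2 = {c.get("data-block"): float(c.get("height")) for c in cells(svg2)}
        assert h1 == h2  # vertical geometry untouched

    def test_region_restricts_visible_blocks(self, toy_matrix):
        svg = render_view(toy_matrix, None, self.config(region=(10, 30)))
        assert {c.get("data-block") for c in cells(svg)} == {"b2", "b3"}

    def test_region_outside_extent_raises(self, toy_matrix):
        with pytest.raises(PavModelError):
            render_view(toy_matrix, None, self.config(region=(0, 10_000)))
        with pytest.raises(PavModelError):
            render_view(toy_matrix, None, self.config(region=(30, 10)))

    def test_genome_order_reorders_rows(self, toy_matrix):
        cfg = self.config(genome_order=["C", "A", "B"])
        svg = render_view(toy_matrix, None, cfg)
        row_y = {}
        for c in cells(svg):
            row_y.setdefault(c.get("data-genome"), float(c.get("y")))
        assert row_y["C"] < row_y["A"] < row_y["B"]
        with pytest.raises(PavModelError):
            render_view(toy_matrix, None, self.config(genome_order=["A", "B"]))

    def test_empty_annotation_set_yields_no_swarm_marks(self, toy_matrix):
        svg = render_view(toy_matrix, [], self.config(show_annotations=True))
        assert 'class="swarm"' not in svg

    def test_swarm_marks_carry_titles_and_lanes(self, toy_matrix):
        gff = (
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t40\t.\t+\t.\tID=gA;Note=alpha\n"
            "chr1\tsrc\tgene\t20\t55\t.\t+\t.\tID=gB;Note=beta\n"
        )
        cards = read_annotations(gff, toy_matrix)
        svg = render_view(toy_matrix, cards, self.config(show_annotations=True, px_per_bp=1.0))
        root = ET.fromstring(svg)
        marks = [e for e in root.iter(f"{SVG_NS}rect") if e.get("class") == "swarm"]
        assert {m.get("data-feature") for m in marks} == {"gA", "gB"}
        assert {m.get("data-lane") for m in marks} == {"0", "1"}  # overlapping spans
        titles = [t.text for m in marks for t in m.iter(f"{SVG_NS}title")]
        assert "gA: alpha" in titles

    def test_output_is_wellformed_svg_with_all_tracks(self):
        m = generate_matrix(FixtureSpec(
            n_genomes=4, n_blocks=30, seed=2,
            planted_repeats=(("chr1_b0004", "chr1_b0011"),),
        ))
        cards = read_annotations(generate_gff3(m, 5, seed=2), m)
        svg = render_view(m, cards, ViewConfig(panchromosome="chr1"))
        root = ET.fromstring(svg)  # parses as XML
        classes = {e.get("class") for e in root.iter(f"{SVG_NS}rect")}
        assert {"overview-bin", "swarm", "status", "repeat", "cell"} <= classes
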