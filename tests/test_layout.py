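"""Layout geometry, checked against independent recomputations."""

import dataclasses
import math

import numpy as np
import pytest

import synplot as sp
from synplot.layout import DotMark, block_extent, genomic_to_x, polar_point
from synplot.render import _flatten, primitive_path

from conftest import config_for

TWO_PI = 2.0 * math.pi


def tiny_dataset(lengths, blocks=(), species_prefixes=None):
    """Dataset with one synthetic gene pinning each chromosome length."""
    genes = []
    for i, (chrom, length) in enumerate(lengths.items()):
        genes.append(sp.GeneRecord(f"pin{i}", chrom, 1, length))
    genomes = sp.build_genome_models(genes)
    return sp.join_and_validate(genomes, list(blocks), "strict")


class TestCircularLayout:
    def test_single_chromosome_full_circle(self):
        ds = tiny_dataset({"os01": 500})
        cfg = config_for("circle", gap_angle=0.0)
        layout = sp.circular_layout(ds, cfg)
        (span,) = layout.spans
        assert span.theta_start == 0.0
        assert span.theta_end == pytest.approx(TWO_PI, abs=1e-12)

    def test_two_equal_chromosomes_symmetric(self):
        g = 0.05
        ds = tiny_dataset({"os01": 500, "os02": 500})
        layout = sp.circular_layout(ds, config_for("circle", gap_angle=g))
        for span in layout.spans:
            assert span.theta_end - span.theta_start == \
                pytest.approx(math.pi - g, abs=1e-12)

    def test_proportional_spans_match_formula(self):
        # independent evaluation of the proportional-span formula
        lengths = {"os01": 100, "os02": 200, "os03": 300}
        gap = 0.1
        ds = tiny_dataset(lengths)
        layout = sp.circular_layout(ds, config_for("circle", gap_angle=gap))
        usable = TWO_PI - 3 * gap
        expected = [usable * l / 600.0 for l in (100, 200, 300)]
        got = [s.theta_end - s.theta_start for s in layout.spans]
        assert got == pytest.approx(expected, abs=1e-12)
        total = sum(got) + 3 * gap
        assert total == pytest.approx(TWO_PI, abs=1e-9)

    def test_arc_closure_on_fixture(self, rice_dataset, config):
        layout = sp.circular_layout(rice_dataset, config)
        total = sum(s.theta_end - s.theta_start for s in layout.spans)
        assert total + len(layout.spans) * config.gap_angle == \
            pytest.approx(TWO_PI, abs=1e-9)

    def test_arcs_pairwise_disjoint(self, rice_dataset, config):
        layout = sp.circular_layout(rice_dataset, config)
        spans = sorted(layout.spans, key=lambda s: s.theta_start)
        for a, b in zip(spans, spans[1:]):
            assert a.theta_end < b.theta_start

    def test_excessive_gap_rejected(self):
        ds = tiny_dataset({"os01": 10, "os02": 10})
        with pytest.raises(sp.LayoutError, match="gap"):
            sp.circular_layout(ds, config_for("circle", gap_angle=math.pi))


class TestGenomicToAngle:
    @pytest.fixture
    def layout(self, rice_dataset, config):
        return sp.circular_layout(rice_dataset, config)

    def test_boundaries(self, layout):
        span = layout.spans[0]
        length = layout.meta["chrom_lengths"][span.chrom_id]
        assert sp.genomic_to_angle(span.chrom_id, 1, layout) == span.theta_start
        assert sp.genomic_to_angle(span.chrom_id, length, layout) == span.theta_end

    def test_matches_independent_interpolator(self, layout):
        rng = np.random.default_rng(2024)
        chroms = [s.chrom_id for s in layout.spans]
        for _ in range(1000):
            cid = chroms[rng.integers(len(chroms))]
            span = layout.span_for(cid)
            length = layout.meta["chrom_lengths"][cid]
            pos = int(rng.integers(1, length + 1))
            oracle = float(np.interp(
                pos, [1, length], [span.theta_start, span.theta_end]
            ))
            assert sp.genomic_to_angle(cid, pos, layout) == \
                pytest.approx(oracle, abs=1e-12)

    def test_out_of_range_rejected(self, layout):
        cid = layout.spans[0].chrom_id
        length = layout.meta["chrom_lengths"][cid]
        with pytest.raises(sp.LayoutError, match="outside"):
            sp.genomic_to_angle(cid, length + 1, layout)

    def test_strictly_increasing_within_chromosome(self, layout):
        cid = layout.spans[0].chrom_id
        length = layout.meta["chrom_lengths"][cid]
        pts = [sp.genomic_to_angle(cid, p, layout)
               for p in np.linspace(1, length, 50)]
        assert all(a < b for a, b in zip(pts, pts[1:]))


class TestRibbons:
    def test_endpoints_lie_on_arcs(self, tmp_path):
        """Ribbon corner points equal polar recomputation from the angles."""
        truth = sp.generate(sp.FixtureParams(
            seed=11,
            species=(sp.SpeciesSpec("aa", 6, 30), sp.SpeciesSpec("bb", 6, 30)),
            n_blocks=200, anchors_per_block=(2, 6), p_cross_species=0.7,
        ))
        ds = sp.join_and_validate(list(truth.genomes), list(truth.blocks))
        cfg = config_for("circle")
        layout = sp.circular_layout(ds, cfg)
        assert len(layout.marks) == len(sp.filter_blocks(ds.blocks, cfg))
        for ribbon in layout.marks:
            center, r = ribbon.center, ribbon.radius
            for theta, pt in zip(
                (*ribbon.arc_a, *ribbon.arc_b),
                (ribbon.endpoints[0], ribbon.endpoints[1],
                 ribbon.endpoints[2], ribbon.endpoints[3]),
            ):
                expected = (center[0] + r * math.sin(theta),
                            center[1] - r * math.cos(theta))
                assert pt == pytest.approx(expected, abs=1e-9)

    def test_default_pinch_places_controls_at_center(self, rice_dataset, config):
        layout = sp.circular_layout(rice_dataset, config)
        center = layout.meta["center"]
        for ribbon in layout.marks:
            for edge in ribbon.control_points:
                for ctrl in edge:
                    assert ctrl == pytest.approx(center, abs=1e-9)

    def test_self_synteny_block_is_valid(self):
        genes = [sp.GeneRecord(f"g{i}", "os01", 100 * i, 100 * i + 50)
                 for i in range(1, 9)]
        blk = sp.SyntenyBlock(
            0, 10.0, 0.0, 2, "os01", "os01", "plus",
            (sp.AnchorPair("g1", "g5", 0, 0), sp.AnchorPair("g2", "g6", 0, 1)),
        )
        ds = sp.join_and_validate(sp.build_genome_models(genes), [blk])
        layout = sp.circular_layout(ds, config_for("circle"))
        (ribbon,) = layout.marks
        assert ribbon.chrom_a == ribbon.chrom_b == "os01"


class TestDotLayout:
    def test_first_bases_map_to_origin_corner(self):
        genes = [
            sp.GeneRecord("a1", "os01", 1, 1), sp.GeneRecord("a2", "os01", 900, 950),
            sp.GeneRecord("b1", "sb01", 1, 1), sp.GeneRecord("b2", "sb01", 800, 850),
        ]
        blk = sp.SyntenyBlock(
            0, 10.0, 0.0, 2, "os01", "sb01", "plus",
            (sp.AnchorPair("a1", "b1", 0, 0), sp.AnchorPair("a2", "b2", 0, 1)),
        )
        ds = sp.join_and_validate(sp.build_genome_models(genes), [blk])
        cfg = config_for("dot")
        layout = sp.dotplot_layout(ds, cfg)
        dots = [m for m in layout.marks if isinstance(m, DotMark)]
        corner = min(dots, key=lambda d: d.x + d.y)
        assert corner.x == pytest.approx(cfg.margin, abs=cfg.margin)
        assert corner.y == pytest.approx(cfg.margin, abs=cfg.margin)

    def test_swapping_axis_genomes_transposes_points(self, rice_dataset):
        fwd = sp.dotplot_layout(rice_dataset, config_for("dot", dual_pair=("os", "sb")))
        rev = sp.dotplot_layout(rice_dataset, config_for("dot", dual_pair=("sb", "os")))
        fwd_pts = sorted((m.x, m.y) for m in fwd.marks if isinstance(m, DotMark))
        rev_pts = sorted((m.y, m.x) for m in rev.marks if isinstance(m, DotMark))
        assert fwd_pts == pytest.approx(rev_pts)

    def test_cumulative_offsets_match_explicit_sum(self, rice_dataset):
        cfg = config_for("dot")
        layout = sp.dotplot_layout(rice_dataset, cfg)
        w, _ = layout.canvas
        chroms = rice_dataset.genomes[0].chromosomes
        span = w - 2 * cfg.margin
        gap = span / 80.0
        scale = (span - (len(chroms) - 1) * gap) / sum(c.length_bp for c in chroms)
        # explicit cumulative sum, written out independently
        cursor = cfg.margin
        for c in chroms:
            assert layout.meta["x_offsets"][c.chrom_id] == \
                pytest.approx(cursor, abs=1e-9)
            cursor += c.length_bp * scale + gap

    def test_orientation_distinguishes_colors(self, rice_dataset, config):
        layout = sp.dotplot_layout(rice_dataset, config_for("dot"))
        dots = [m for m in layout.marks if isinstance(m, DotMark)]
        by_orient = {}
        for blk in rice_dataset.blocks:
            by_orient.setdefault(blk.orientation, set()).add(blk.block_id)
        colors = {o: {d.color for d in dots if d.block_id in ids}
                  for o, ids in by_orient.items()}
        assert len(colors) == 2  # fixture has both orientations
        assert colors["plus"].isdisjoint(colors["minus"])

    def test_unknown_species_pair_rejected(self, rice_dataset):
        with pytest.raises(sp.SynplotError, match="zz"):
            sp.dotplot_layout(rice_dataset, config_for("dot", dual_pair=("os", "zz")))


class TestBarLayout:
    def test_bar_lengths_proportional(self):
        ds = tiny_dataset({"os01": 1000, "os02": 2000})
        layout = sp.bar_layout(ds, config_for("bar"))
        l1, l2 = (s.x_end - s.x_start for s in layout.spans)
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_full_chromosome_block_covers_bar(self):
        genes = [
            sp.GeneRecord("a1", "os01", 1, 50), sp.GeneRecord("a2", "os01", 951, 1000),
            sp.GeneRecord("b1", "sb01", 1, 40), sp.GeneRecord("b2", "sb01", 960, 1000),
        ]
        blk = sp.SyntenyBlock(
            0, 1.0, 0.0, 2, "os01", "sb01", "plus",
            (sp.AnchorPair("a1", "b1", 0, 0), sp.AnchorPair("a2", "b2", 0, 1)),
        )
        ds = sp.join_and_validate(sp.build_genome_models(genes), [blk])
        layout = sp.bar_layout(ds, config_for("bar"))
        span = layout.span_for("os01")
        mark = next(m for m in layout.marks if m.chrom_id == "os01")
        bp_scale = (span.x_end - span.x_start) / 1000
        assert mark.x0 == pytest.approx(span.x_start, abs=bp_scale)
        assert mark.x1 == pytest.approx(span.x_end, abs=bp_scale)

    def test_interval_extents_equal_scale_times_genomic(self, rice_dataset):
        cfg = config_for("bar")
        layout = sp.bar_layout(rice_dataset, cfg)
        scale = layout.meta["scale"]
        marks = {(m.block_id, m.chrom_id): m for m in layout.marks}
        for blk in sp.filter_blocks(rice_dataset.blocks, cfg):
            for side in ("a", "b"):
                chrom, lo, hi = block_extent(blk, side, rice_dataset)
                m = marks[(blk.block_id, chrom)]
                assert m.x1 - m.x0 == pytest.approx((hi - lo) * scale, rel=1e-9)

    def test_matching_intervals_share_color_across_bars(self, rice_dataset):
        layout = sp.bar_layout(rice_dataset, config_for("bar"))
        by_block = {}
        for m in layout.marks:
            by_block.setdefault(m.block_id, set()).add(m.color)
        assert all(len(colors) == 1 for colors in by_block.values())


class TestDualLayout:
    def test_all_cross_species_blocks_drawn(self, rice_dataset, config):
        cfg = config_for("dual")
        layout = sp.dual_synteny_layout(rice_dataset, cfg, ("os", "sb"))
        assert len(layout.marks) == len(sp.filter_blocks(rice_dataset.blocks, cfg))

    def test_no_intra_species_synteny_is_an_error(self, rice_dataset):
        with pytest.raises(sp.LayoutError, match="no synteny"):
            sp.dual_synteny_layout(rice_dataset, config_for("dual"), ("os", "os"))

    def test_band_corners_on_bar_edges(self, rice_dataset):
        layout = sp.dual_synteny_layout(rice_dataset, config_for("dual"), ("os", "sb"))
        for band in layout.marks:
            ls = layout.span_for(band.chrom_a)
            rs = layout.span_for(band.chrom_b)
            (c1, c2, c3, c4) = band.corners
            assert c1[0] == c2[0] == pytest.approx(ls.y + ls.thickness)
            assert c3[0] == c4[0] == pytest.approx(rs.y)
            for c in (c1, c2):
                assert ls.x_start <= c[1] <= ls.x_end
            for c in (c3, c4):
                assert rs.x_start <= c[1] <= rs.x_end


class TestFilterBlocks:
    def make(self, n):
        return sp.SyntenyBlock(
            0, 1.0, 0.0, n, "a1", "b1", "plus",
            tuple(sp.AnchorPair(f"x{i}", f"y{i}", 0, i) for i in range(n)),
        )

    def test_min_two_keeps_two_and_five(self, config):
        blocks = [self.make(1), self.make(2), self.make(5)]
        assert [len(b.anchors) for b in sp.filter_blocks(blocks, config)] == [2, 5]

    def test_empty_list(self, config):
        assert sp.filter_blocks([], config) == []

    def test_survivors_match_histogram_tail(self, rice_truth, config):
        cfg = dataclasses.replace(config, min_block_anchors=6)
        survivors = sp.filter_blocks(rice_truth.blocks, cfg)
        expected = sum(v for k, v in rice_truth.anchor_histogram.items() if k >= 6)
        assert len(survivors) == expected


def all_scene_coordinates(layout, cfg):
    """Every canvas coordinate a renderer will touch."""
    scene = sp.layout_to_scene(layout, cfg)
    for prim in scene.primitives:
        if prim.kind == "text":
            yield prim.geometry[0], prim.geometry[1]
        elif prim.kind == "circle_marker":
            (cx, cy), r = prim.geometry
            yield cx - r, cy - r
            yield cx + r, cy + r
        else:
            yield from _flatten(primitive_path(prim))


class TestCrossPlotInvariants:
    @pytest.mark.parametrize("plot", sp.PLOT_TYPES)
    def test_all_coordinates_inside_canvas(self, rice_dataset, plot):
        cfg = config_for(plot)
        layout = sp.compute_layout(rice_dataset, cfg)
        w, h = layout.canvas
        for x, y in all_scene_coordinates(layout, cfg):
            assert -1e-9 <= x <= w + 1e-9
            assert -1e-9 <= y <= h + 1e-9

    @pytest.mark.parametrize("plot", sp.PLOT_TYPES)
    def test_layout_deterministic(self, rice_dataset, plot):
        cfg = config_for(plot)
        assert sp.compute_layout(rice_dataset, cfg) == \
            sp.compute_layout(rice_dataset, cfg)

    @pytest.mark.parametrize("plot", ["bar", "dot", "dual"])
    def test_linear_layouts_scale_with_canvas(self, rice_dataset, plot):
        """Doubling canvas, margin and font doubles every coordinate."""
        cfg1 = config_for(plot, canvas_width=800.0, canvas_height=600.0)
        cfg2 = config_for(
            plot, canvas_width=1600.0, canvas_height=1200.0,
            margin=2 * cfg1.margin, label_font_size=2 * cfg1.label_font_size,
        )
        pts1 = list(all_scene_coordinates(sp.compute_layout(rice_dataset, cfg1), cfg1))
        pts2 = list(all_scene_coordinates(sp.compute_layout(rice_dataset, cfg2), cfg2))
        assert len(pts1) == len(pts2)
        for (x1, y1), (x2, y2) in zip(pts1, pts2):
            assert x2 == pytest.approx(2 * x1, rel=1e-9, abs=1e-6)
            assert y2 == pytest.approx(2 * y1, rel=1e-9, abs=1e-6)

    def test_circle_angles_independent_of_canvas(self, rice_dataset):
        small = sp.circular_layout(rice_dataset, config_for(
            "circle", canvas_width=500.0, canvas_height=500.0))
        large = sp.circular_layout(rice_dataset, config_for(
            "circle", canvas_width=2000.0, canvas_height=2000.0))
        for s1, s2 in zip(small.spans, large.spans):
            assert (s1.theta_start, s1.theta_end) == (s2.theta_start, s2.theta_end)

    def test_monotone_linear_map(self, rice_dataset):
        layout = sp.bar_layout(rice_dataset, config_for("bar"))
        cid = layout.spans[0].chrom_id
        length = layout.meta["chrom_lengths"][cid]
        xs = [genomic_to_x(cid, p, layout) for p in np.linspace(1, length, 50)]
        assert all(a < b for a, b in zip(xs, xs[1:]))
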