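"""Pure geometry: map the genomic model onto canvas coordinates.

Four plot archetypes are supported:

* ``circle`` — all chromosomes as arcs on one ring, collinear blocks as
  chord ribbons (circular ideogram).
* ``bar``    — one horizontal bar per chromosome, blocks painted as
  matching colored intervals on both partner bars.
* ``dot``    — macrosynteny dot plot, one point per anchor pair, axes
  are base-pair-cumulative concatenations of two genomes.
* ``dual``   — two facing columns of chromosome bars with quadrilateral
  bands joining collinear regions of a chosen species pair.

Canvas convention (honored by every renderer): origin at the top-left,
y increases downward, units are points; angle 0 is at 12 o'clock and
increases clockwise.  Genomic coordinates are 1-based inclusive; this
module is the only place they are converted to canvas space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io import PlotConfig
from .model import SynplotError, SyntenyBlock, SyntenyDataset

__all__ = [
    "ArcSpan",
    "LinearSpan",
    "RibbonGeometry",
    "IntervalMark",
    "BandMark",
    "DotMark",
    "SegmentMark",
    "Label",
    "LayoutResult",
    "LayoutError",
    "filter_blocks",
    "circular_layout",
    "bar_layout",
    "dotplot_layout",
    "dual_synteny_layout",
    "compute_layout",
    "genomic_to_angle",
    "polar_point",
    "block_extent",
]

TWO_PI = 2.0 * math.pi

# Internal proportions, all relative to the canvas so that scaling the
# canvas (with margin and font scaled alike) scales every coordinate.
AXIS_GAP_FRAC = 1.0 / 80.0    # dot plot: inter-chromosome gap / axis span
COLUMN_GAP_FRAC = 1.0 / 80.0  # dual plot: vertical gap / column span
BAR_FILL_FRAC = 0.45          # bar plot: bar height / track height
DUAL_BAR_FRAC = 0.018         # dual plot: bar width / canvas width
RING_BAND_FRAC = 0.045        # circle plot: band thickness / ring radius


class LayoutError(SynplotError):
    """The requested geometry is impossible for this dataset/config."""


@dataclass(frozen=True)
class ArcSpan:
    """One chromosome as an arc of the ideogram ring."""

    chrom_id: str
    theta_start: float
    theta_end: float
    radius: float  # ribbon attachment radius (inner edge of the band)


@dataclass(frozen=True)
class LinearSpan:
    """One chromosome as a bar.

    ``x_start``/``x_end`` run along the bar's own axis.  For horizontal
    bars ``y`` is the top edge; for vertical bars (``vertical=True``,
    dual-synteny columns) the along-axis coordinates are canvas-y values
    and ``y`` holds the bar's left canvas-x edge.
    """

    chrom_id: str
    x_start: float
    x_end: float
    y: float
    track: int
    thickness: float = 0.0
    vertical: bool = False


@dataclass(frozen=True)
class RibbonGeometry:
    """A chord ribbon: two arc edges joined by two cubic Bezier edges.

    ``endpoints`` are (P1, P2, P3, P4): P1/P2 bound the block extent on
    chromosome A, P3/P4 on chromosome B.  Each curved edge runs P2->P3
    and P4->P1 with the two interior ``control_points`` pulled toward the
    ring center (factor 0 places them at the center — the classic chord
    pinch).
    """

    block_id: int
    endpoints: tuple[tuple[float, float], ...]
    control_points: tuple[tuple[tuple[float, float], tuple[float, float]], ...]
    fill_color: str
    opacity: float
    chrom_a: str
    chrom_b: str
    arc_a: tuple[float, float] = (0.0, 0.0)  # theta range on chromosome A
    arc_b: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 0.0


@dataclass(frozen=True)
class IntervalMark:
    """Bar plot: one block's colored interval on one chromosome bar."""

    block_id: int
    chrom_id: str
    x0: float
    x1: float
    y: float
    height: float
    color: str


@dataclass(frozen=True)
class BandMark:
    """Dual plot: quadrilateral joining block extents on two bars."""

    block_id: int
    corners: tuple[tuple[float, float], ...]
    color: str
    opacity: float
    chrom_a: str
    chrom_b: str


@dataclass(frozen=True)
class DotMark:
    block_id: int
    x: float
    y: float
    color: str
    chrom_x: str
    chrom_y: str


@dataclass(frozen=True)
class SegmentMark:
    x0: float
    y0: float
    x1: float
    y1: float
    color: str = "#C7C7C7"
    width: float = 0.75


@dataclass(frozen=True)
class Label:
    text: str
    x: float
    y: float
    rotation: float = 0.0  # degrees, clockwise about the anchor
    anchor: str = "middle"  # start | middle | end
    font_size: float = 12.0


@dataclass(frozen=True)
class LayoutResult:
    plot_type: str
    canvas: tuple[float, float]
    spans: tuple
    marks: tuple
    labels: tuple[Label, ...]
    meta: dict = field(default_factory=dict)
    dataset: SyntenyDataset | None = field(
        default=None, repr=False, compare=False
    )

    def span_for(self, chrom_id: str):
        for s in self.spans:
            if s.chrom_id == chrom_id:
                return s
        raise KeyError(f"no span for chromosome {chrom_id!r}")


def polar_point(
    center: tuple[float, float], radius: float, theta: float
) -> tuple[float, float]:
    """Canvas point at ``theta`` (0 = 12 o'clock, clockwise positive)."""
    return (
        center[0] + radius * math.sin(theta),
        center[1] - radius * math.cos(theta),
    )


def filter_blocks(
    blocks: tuple[SyntenyBlock, ...] | list[SyntenyBlock], config: PlotConfig
) -> list[SyntenyBlock]:
    """Drop blocks with fewer than ``min_block_anchors`` anchors (stable)."""
    return [b for b in blocks if len(b.anchors) >= config.min_block_anchors]


def block_extent(
    block: SyntenyBlock, side: str, dataset: SyntenyDataset
) -> tuple[str, int, int]:
    """Genomic extent of a block on one side: (chrom, min start, max end)."""
    genes = [
        dataset.gene_index[a.gene_a if side == "a" else a.gene_b][2]
        for a in block.anchors
    ]
    chrom = block.chrom_a if side == "a" else block.chrom_b
    return chrom, min(g.start for g in genes), max(g.end for g in genes)


def _interp(pos: float, length: int, lo: float, hi: float) -> float:
    """Map 1-based pos in [1, length] linearly onto [lo, hi] (endpoints
    inclusive) — the angle convention: pos 1 at lo, pos length at hi."""
    if length <= 1:
        return 0.5 * (lo + hi)
    return lo + (pos - 1.0) / (length - 1.0) * (hi - lo)


def _linear(pos: float, length: int, lo: float, hi: float) -> float:
    """Map a base to its cell midpoint: lo + (pos - 0.5) * scale.

    Each of the ``length`` bases owns a cell of width (hi-lo)/length, so
    the per-bp scale is exactly the global scale and a genomic extent of
    d bases always spans d * scale points regardless of chromosome.
    """
    return lo + (pos - 0.5) * (hi - lo) / length


def genomic_to_angle(chrom_id: str, pos_bp: float, layout: LayoutResult) -> float:
    """Angle of a genomic position on a circular layout (radians)."""
    span = layout.span_for(chrom_id)
    length = layout.meta["chrom_lengths"][chrom_id]
    if not 1 <= pos_bp <= length:
        raise LayoutError(
            f"position {pos_bp} outside chromosome {chrom_id!r} [1, {length}]"
        )
    return _interp(pos_bp, length, span.theta_start, span.theta_end)


def genomic_to_x(chrom_id: str, pos_bp: float, layout: LayoutResult) -> float:
    """Along-bar coordinate of a genomic position on a linear layout."""
    span = layout.span_for(chrom_id)
    length = layout.meta["chrom_lengths"][chrom_id]
    if not 1 <= pos_bp <= length:
        raise LayoutError(
            f"position {pos_bp} outside chromosome {chrom_id!r} [1, {length}]"
        )
    return _linear(pos_bp, length, span.x_start, span.x_end)


# --------------------------------------------------------------------------
# Circle plot
# --------------------------------------------------------------------------


def circular_layout(dataset: SyntenyDataset, config: PlotConfig) -> LayoutResult:
    """Circular ideogram: arcs proportional to chromosome length.

    Arc span_i = (2*pi - C*gap_angle) * length_i / total_length, arcs laid
    clockwise from 12 o'clock in canonical chromosome order; one chord
    ribbon per block spanning the block's genomic extent on each side.
    """
    chroms = dataset.chromosomes
    if not chroms:
        raise LayoutError("no chromosomes to lay out")
    nch = len(chroms)
    gap = config.gap_angle
    if nch * gap >= TWO_PI:
        raise LayoutError(
            f"gap_angle too large: {nch} gaps of {gap:.4f} rad exceed 2*pi"
        )
    w, h = config.resolved_canvas()
    cx, cy = w / 2.0, h / 2.0
    avail = min(w, h) / 2.0 - config.margin
    if avail <= 0:
        raise LayoutError("margin leaves no drawable ring")
    fs = config.label_font_size
    r_outer = avail - 2.2 * fs
    thickness = max(4.0, RING_BAND_FRAC * avail)
    r_inner = r_outer - thickness
    if r_inner <= 0:
        raise LayoutError("canvas too small for the ideogram ring")

    total_len = float(sum(c.length_bp for c in chroms))
    usable = TWO_PI - nch * gap

    spans: list[ArcSpan] = []
    labels: list[Label] = []
    cursor = 0.0
    chrom_index: dict[str, int] = {}
    for i, c in enumerate(chroms):
        span_angle = usable * c.length_bp / total_len
        spans.append(ArcSpan(c.chrom_id, cursor, cursor + span_angle, r_inner))
        mid = cursor + span_angle / 2.0
        lx, ly = polar_point((cx, cy), avail - 0.8 * fs, mid)
        labels.append(Label(c.chrom_id, lx, ly, math.degrees(mid), "middle", fs))
        chrom_index[c.chrom_id] = i
        cursor += span_angle + gap

    result = LayoutResult(
        plot_type="circle",
        canvas=(w, h),
        spans=tuple(spans),
        marks=(),
        labels=tuple(labels),
        meta={
            "center": (cx, cy),
            "r_inner": r_inner,
            "r_outer": r_outer,
            "band_thickness": thickness,
            "chrom_lengths": {c.chrom_id: c.length_bp for c in chroms},
            "chrom_index": chrom_index,
        },
        dataset=dataset,
    )

    blocks = filter_blocks(dataset.blocks, config)
    ribbons = tuple(ribbon_for_block(b, result, config) for b in blocks)
    return LayoutResult(
        result.plot_type, result.canvas, result.spans, ribbons,
        result.labels, result.meta, dataset,
    )


def ribbon_for_block(
    block: SyntenyBlock, layout: LayoutResult, config: PlotConfig
) -> RibbonGeometry:
    """Chord ribbon for one block on a circular layout."""
    dataset = layout.dataset
    if dataset is None:
        raise LayoutError("layout carries no dataset; cannot resolve genes")
    _, a_lo, a_hi = block_extent(block, "a", dataset)
    _, b_lo, b_hi = block_extent(block, "b", dataset)
    center = layout.meta["center"]
    r = layout.span_for(block.chrom_a).radius

    th = [
        genomic_to_angle(block.chrom_a, a_lo, layout),
        genomic_to_angle(block.chrom_a, a_hi, layout),
        genomic_to_angle(block.chrom_b, b_lo, layout),
        genomic_to_angle(block.chrom_b, b_hi, layout),
    ]
    p1, p2, p3, p4 = (polar_point(center, r, t) for t in th)

    def pinch(p: tuple[float, float]) -> tuple[float, float]:
        f = config.ribbon_pinch
        return (
            center[0] + f * (p[0] - center[0]),
            center[1] + f * (p[1] - center[1]),
        )

    return RibbonGeometry(
        block_id=block.block_id,
        endpoints=(p1, p2, p3, p4),
        control_points=((pinch(p2), pinch(p3)), (pinch(p4), pinch(p1))),
        fill_color=config.color(layout.meta["chrom_index"][block.chrom_a]),
        opacity=config.ribbon_opacity,
        chrom_a=block.chrom_a,
        chrom_b=block.chrom_b,
        arc_a=(th[0], th[1]),
        arc_b=(th[2], th[3]),
        center=center,
        radius=r,
    )


# --------------------------------------------------------------------------
# Bar plot
# --------------------------------------------------------------------------


def bar_layout(dataset: SyntenyDataset, config: PlotConfig) -> LayoutResult:
    """Stacked horizontal chromosome bars with per-block matched intervals.

    All bars share one global bp-to-point scale and a common left edge;
    each surviving block paints the same palette color on both partner
    bars over the block's genomic extent, so matching regions can be read
    off by color.
    """
    chroms = dataset.chromosomes
    if not chroms:
        raise LayoutError("no chromosomes to lay out")
    w, h = config.resolved_canvas()
    fs = config.label_font_size
    label_space = 5.0 * fs
    x0 = config.margin + label_space
    x1 = w - config.margin
    if x1 <= x0:
        raise LayoutError("canvas too narrow for bars")
    max_len = max(c.length_bp for c in chroms)
    scale = (x1 - x0) / max_len

    track_h = (h - 2.0 * config.margin) / len(chroms)
    bar_h = BAR_FILL_FRAC * track_h

    spans: list[LinearSpan] = []
    labels: list[Label] = []
    for i, c in enumerate(chroms):
        y_top = config.margin + i * track_h + (track_h - bar_h) / 2.0
        spans.append(
            LinearSpan(c.chrom_id, x0, x0 + c.length_bp * scale,
                       y_top, i, bar_h)
        )
        labels.append(
            Label(c.chrom_id, x0 - 0.5 * fs, y_top + bar_h / 2.0,
                  0.0, "end", fs)
        )

    result = LayoutResult(
        plot_type="bar",
        canvas=(w, h),
        spans=tuple(spans),
        marks=(),
        labels=tuple(labels),
        meta={
            "scale": scale,
            "chrom_lengths": {c.chrom_id: c.length_bp for c in chroms},
        },
        dataset=dataset,
    )

    marks: list[IntervalMark] = []
    for bi, block in enumerate(filter_blocks(dataset.blocks, config)):
        color = config.color(bi)
        for side in ("a", "b"):
            chrom, lo, hi = block_extent(block, side, dataset)
            span = result.span_for(chrom)
            marks.append(
                IntervalMark(
                    block.block_id, chrom,
                    genomic_to_x(chrom, lo, result),
                    genomic_to_x(chrom, hi, result),
                    span.y, span.thickness, color,
                )
            )
    return LayoutResult(
        result.plot_type, result.canvas, result.spans, tuple(marks),
        result.labels, result.meta, dataset,
    )


# --------------------------------------------------------------------------
# Dot plot
# --------------------------------------------------------------------------


def _axis_spans(
    chroms, lo: float, hi: float
) -> tuple[list[tuple[str, float, float]], float]:
    """Cumulative chromosome intervals along one axis, with fixed gaps."""
    span = hi - lo
    gap = AXIS_GAP_FRAC * span
    total = float(sum(c.length_bp for c in chroms))
    scale = (span - (len(chroms) - 1) * gap) / total
    if scale <= 0:
        raise LayoutError("axis too short for the chromosome count")
    out = []
    cursor = lo
    for c in chroms:
        extent = c.length_bp * scale
        out.append((c.chrom_id, cursor, cursor + extent))
        cursor += extent + gap
    return out, scale


def dotplot_layout(dataset: SyntenyDataset, config: PlotConfig) -> LayoutResult:
    """Macrosynteny dot plot: one point per anchor pair at gene midpoints.

    The x axis concatenates genome A's chromosomes (cumulative base-pair
    offsets with a fixed inter-chromosome gap), the y axis genome B's;
    a single-genome dataset uses all chromosomes on both axes.  Points
    are colored by block orientation (plus vs minus strand blocks).
    """
    blocks = filter_blocks(dataset.blocks, config)
    if not blocks:
        raise LayoutError("no blocks to plot")
    if config.dual_pair is not None:
        try:
            ga = dataset.genome(config.dual_pair[0])
            gb = dataset.genome(config.dual_pair[1])
        except KeyError as exc:
            raise LayoutError(str(exc)) from None
    elif len(dataset.genomes) >= 2:
        ga, gb = dataset.genomes[0], dataset.genomes[1]
    else:
        ga = gb = dataset.genomes[0]

    w, h = config.resolved_canvas()
    m = config.margin
    fs = config.label_font_size
    x_chroms = list(ga.chromosomes)
    y_chroms = list(gb.chromosomes)
    xs, x_scale = _axis_spans(x_chroms, m, w - m)
    ys, y_scale = _axis_spans(y_chroms, m, h - m)

    spans: list[LinearSpan] = []
    labels: list[Label] = []
    grid: list[SegmentMark] = []
    for i, (cid, a, b) in enumerate(xs):
        spans.append(LinearSpan(cid, a, b, h - m, i, 0.0, False))
        labels.append(Label(cid, (a + b) / 2.0, h - m + 1.2 * fs, 0.0, "middle", fs))
        grid.append(SegmentMark(a, m, a, h - m))
        grid.append(SegmentMark(b, m, b, h - m))
    for i, (cid, a, b) in enumerate(ys):
        spans.append(LinearSpan(cid, a, b, m, i, 0.0, True))
        labels.append(Label(cid, m - 0.6 * fs, (a + b) / 2.0, -90.0, "middle", fs))
        grid.append(SegmentMark(m, a, w - m, a))
        grid.append(SegmentMark(m, b, w - m, b))

    x_pos = {cid: (a, b) for cid, a, b in xs}
    y_pos = {cid: (a, b) for cid, a, b in ys}
    len_by_id = {c.chrom_id: c.length_bp for c in (*x_chroms, *y_chroms)}

    plus_color, minus_color = config.palette[0], config.palette[1 % len(config.palette)]
    dots: list[DotMark] = []
    for block in blocks:
        on_axes = block.chrom_a in x_pos and block.chrom_b in y_pos
        swapped = block.chrom_b in x_pos and block.chrom_a in y_pos
        if not (on_axes or swapped):
            continue
        color = plus_color if block.orientation == "plus" else minus_color
        for anchor in block.anchors:
            g1 = dataset.gene_index[anchor.gene_a][2]
            g2 = dataset.gene_index[anchor.gene_b][2]
            if on_axes:
                gx, gy = g1, g2
            else:
                gx, gy = g2, g1
            xa, xb = x_pos[gx.chrom_id]
            ya, yb = y_pos[gy.chrom_id]
            dots.append(
                DotMark(
                    block.block_id,
                    _linear(gx.midpoint, len_by_id[gx.chrom_id], xa, xb),
                    _linear(gy.midpoint, len_by_id[gy.chrom_id], ya, yb),
                    color, gx.chrom_id, gy.chrom_id,
                )
            )
    if not dots:
        raise LayoutError(
            f"no anchors join genomes {ga.species_tag!r} and {gb.species_tag!r}"
        )

    return LayoutResult(
        plot_type="dot",
        canvas=(w, h),
        spans=tuple(spans),
        marks=tuple(grid) + tuple(dots),
        labels=tuple(labels),
        meta={
            "x_scale": x_scale,
            "y_scale": y_scale,
            "x_offsets": {cid: a for cid, a, _ in xs},
            "y_offsets": {cid: a for cid, a, _ in ys},
            "chrom_lengths": len_by_id,
        },
        dataset=dataset,
    )


# --------------------------------------------------------------------------
# Dual synteny plot
# --------------------------------------------------------------------------


def dual_synteny_layout(
    dataset: SyntenyDataset,
    config: PlotConfig,
    pair: tuple[str, str] | None = None,
) -> LayoutResult:
    """Two facing columns of chromosome bars joined by synteny bands."""
    if pair is None:
        pair = config.dual_pair
    if pair is None:
        tags = [g.species_tag for g in dataset.genomes]
        if len(tags) < 2:
            raise LayoutError(
                "dual synteny plot needs two species (or an explicit pair)"
            )
        pair = (tags[0], tags[1])
    try:
        left_g = dataset.genome(pair[0])
        right_g = dataset.genome(pair[1])
    except KeyError as exc:
        raise LayoutError(str(exc)) from None

    w, h = config.resolved_canvas()
    m = config.margin
    fs = config.label_font_size
    bw = DUAL_BAR_FRAC * w
    label_space = 5.0 * fs
    lx0 = m + label_space
    rx1 = w - m - label_space
    if rx1 - bw <= lx0 + bw:
        raise LayoutError("canvas too narrow for two columns")

    def column(genome, bar_x: float, base_track: int):
        chroms = list(genome.chromosomes)
        span = h - 2.0 * m
        vgap = COLUMN_GAP_FRAC * span
        total = float(sum(c.length_bp for c in chroms))
        scale = (span - (len(chroms) - 1) * vgap) / total
        if scale <= 0:
            raise LayoutError("canvas too short for the chromosome count")
        out = []
        cursor = m
        for i, c in enumerate(chroms):
            extent = c.length_bp * scale
            out.append(
                LinearSpan(c.chrom_id, cursor, cursor + extent,
                           bar_x, base_track + i, bw, True)
            )
            cursor += extent + vgap
        return out

    left_spans = column(left_g, lx0, 0)
    right_spans = column(right_g, rx1 - bw, len(left_spans))
    spans = tuple(left_spans + right_spans)

    labels: list[Label] = []
    for s in left_spans:
        labels.append(Label(s.chrom_id, lx0 - 0.5 * fs,
                            (s.x_start + s.x_end) / 2.0, 0.0, "end", fs))
    for s in right_spans:
        labels.append(Label(s.chrom_id, rx1 - bw + bw + 0.5 * fs,
                            (s.x_start + s.x_end) / 2.0, 0.0, "start", fs))

    lengths = {
        c.chrom_id: c.length_bp
        for g in (left_g, right_g)
        for c in g.chromosomes
    }
    chrom_index = {s.chrom_id: i for i, s in enumerate(spans)}
    result = LayoutResult(
        plot_type="dual",
        canvas=(w, h),
        spans=spans,
        marks=(),
        labels=tuple(labels),
        meta={"pair": pair, "chrom_lengths": lengths,
              "chrom_index": chrom_index},
        dataset=dataset,
    )

    left_ids = {c.chrom_id for c in left_g.chromosomes}
    right_ids = {c.chrom_id for c in right_g.chromosomes}
    bands: list[BandMark] = []
    for block in filter_blocks(dataset.blocks, config):
        if block.chrom_a in left_ids and block.chrom_b in right_ids:
            la, ra = "a", "b"
        elif block.chrom_b in left_ids and block.chrom_a in right_ids:
            la, ra = "b", "a"
        else:
            continue
        lc, llo, lhi = block_extent(block, la, dataset)
        rc, rlo, rhi = block_extent(block, ra, dataset)
        ls, rs = result.span_for(lc), result.span_for(rc)
        ly0 = _linear(llo, lengths[lc], ls.x_start, ls.x_end)
        ly1 = _linear(lhi, lengths[lc], ls.x_start, ls.x_end)
        ry0 = _linear(rlo, lengths[rc], rs.x_start, rs.x_end)
        ry1 = _linear(rhi, lengths[rc], rs.x_start, rs.x_end)
        x_left = ls.y + ls.thickness  # right edge of the left bar
        x_right = rs.y                # left edge of the right bar
        bands.append(
            BandMark(
                block.block_id,
                ((x_left, ly0), (x_left, ly1), (x_right, ry1), (x_right, ry0)),
                config.color(chrom_index[lc]),
                config.ribbon_opacity,
                lc, rc,
            )
        )
    if not bands:
        raise LayoutError(f"no synteny between {pair[0]!r} and {pair[1]!r}")

    return LayoutResult(
        result.plot_type, result.canvas, result.spans, tuple(bands),
        result.labels, result.meta, dataset,
    )


def compute_layout(dataset: SyntenyDataset, config: PlotConfig) -> LayoutResult:
    """Dispatch on config.plot_type."""
    if config.plot_type == "circle":
        return circular_layout(dataset, config)
    if config.plot_type == "bar":
        return bar_layout(dataset, config)
    if config.plot_type == "dot":
        return dotplot_layout(dataset, config)
    if config.plot_type == "dual":
        return dual_synteny_layout(dataset, config)
    raise LayoutError(f"unknown plot type {config.plot_type!r}")
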