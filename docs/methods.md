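# Methods

## Data model

The pipeline joins two inputs into one validated dataset. Genomic
coordinates are 1-based and inclusive (the GFF convention) everywhere in
the model; conversion to canvas space happens only in the layout stage.

A genome is reconstructed from the annotation alone: genes are grouped
by chromosome id, chromosomes by species tag — the leading alphabetic
run of the chromosome id (`os01` → `os`), overridable with a regex for
other naming schemes. Chromosome extent is the maximum gene end on that
chromosome unless the control file supplies an explicit length, because
the input triad carries no karyotype file; this underestimates true
chromosome length by the terminal gene-free tail, which affects only the
proportional widths of the drawn ideograms, not block geometry.
Chromosomes are natural-sorted (`os2` before `os10`) and genomes sorted
by species tag, so model construction is invariant under permutation of
the annotation lines.

Joining collinearity with annotation ("validation") resolves every
anchor gene id against the gene index. Two policies:

* `strict` (default): any unresolvable anchor, or any block header
  naming a genuinely different chromosome than its anchors sit on, is a
  hard error naming the gene and block. Spelling-only disagreements —
  MCScanX headers drop zero padding (`os1` vs `os01`) — are reconciled
  silently by normalizing to (species prefix, integer suffix).
* `drop`: offending anchors are removed, blocks left with fewer than
  two anchors are removed, header tags are rewritten from the
  annotation, and all removals are counted in a report that the CLI
  echoes. Strict is the default so dirty data fails loudly; `drop` is
  an explicit opt-in.

## Layout geometry

One canvas convention for all plots and renderers: origin top-left,
y down, units printer's points; angle 0 at 12 o'clock increasing
clockwise (the ideogram convention).

**Block extent.** A block's footprint on a chromosome is
[min gene start, max gene end] over that side's anchors. Detection
tools report only the anchor list, so some extent convention is
required; the anchor hull is the tightest interval containing every
paired gene.

**Circle.** With C chromosomes, gap angle g (default 2°) and lengths
Lᵢ, arc i spans (2π − C·g)·Lᵢ/ΣL; arcs are laid clockwise from
12 o'clock in canonical order, so Σspans + C·g = 2π by construction.
All genomes share one ring. A genomic position maps to an angle by
endpoint interpolation: θ(p) = θ₀ + (p−1)/(L−1)·(θ₁−θ₀) (midpoint for
L = 1). Ribbons attach at the band's inner radius; each ribbon is two
arc edges joined by two cubic Bézier edges whose interior control
points are the chord endpoints pulled toward the ring center by a
configurable factor (default 0, i.e. control points at the center —
the classic chord-diagram pinch). Ribbon fill is the palette color of
the block's first chromosome; default opacity 0.45 so crossing ribbons
stay readable.

**Linear maps (bar, dot, dual).** Each base owns a cell of width
span/L points, and position p maps to its cell midpoint
x(p) = x₀ + (p − 0.5)·scale. This makes the per-bp scale exactly the
global scale on every bar — a genomic extent of d bases always spans
d·scale points — at the cost of half-a-base margins at bar ends
(sub-pixel at any realistic scale). The circle keeps the endpoint
convention above because arc ends are visually meaningful there.

**Bar.** One track per chromosome, stacked in canonical order, all
left-aligned, lengths on a single global scale set by the longest
chromosome. Each surviving block paints its extent on both partner bars
in a per-block color cycling the palette, so matched regions are read
off by color.

**Dot.** The x axis concatenates genome A's chromosomes with cumulative
base-pair offsets and a fixed inter-chromosome gap of 1/80 of the axis
span; the y axis likewise for genome B (a single-genome dataset uses
all chromosomes on both axes; `dual_pair` selects axes explicitly).
Each anchor is one point at the two genes' midpoints. Points are
colored by the block's orientation token (plus/minus → first two
palette entries), so inversions stand out as anti-diagonal runs.
Chromosome-boundary gridlines and axis labels are included.

**Dual synteny.** Two facing columns of vertical chromosome bars
(bar width 1.8 % of canvas width, inter-bar gap 1/80 of the column
span, per-column global scales). Blocks joining the selected species
pair become quadrilateral bands from the block's extent on the left
bar's right edge to its extent on the right bar's left edge; blocks not
joining the pair are excluded, and a pair with no joining blocks is an
error. Band color follows the left chromosome.

Internal proportions (axis gaps, bar widths, label offsets) are
fractions of the canvas or of the font size, so scaling canvas, margin
and font together scales every coordinate exactly; layouts are pure
functions of (dataset, config) and bit-for-bit deterministic.

Blocks with fewer than `min_block_anchors` anchors (default 2) are
filtered before layout in every plot type; a single shared gene pair is
not evidence of a conserved segment.

## Scene graph and rendering

Layouts serialize to a backend-neutral scene: an ordered painter's list
of six primitive kinds (arc band, cubic ribbon, polygon, segment,
circle marker, text) drawn spans → marks → labels. Every primitive
carries either a fill or a stroke, never both, so each maps to exactly
one drawable element in every backend — which makes element counts a
checkable contract.

The SVG, EPS and PDF writers are part of this package and are written
for determinism: fixed decimal formatting (3 decimals, trailing zeros
stripped), no timestamps, no generator strings, no randomized ids;
identical scenes yield byte-identical files. Arcs are converted to
cubic Bézier segments (≤ 90° apiece, the standard 4/3·tan(Δ/4) control
factor, radial error < 3·10⁻⁴·r) so all three vector writers consume
one path representation. Specifics:

* SVG 1.1: one `<path>`/`<circle>`/`<text>` element per primitive plus
  a background rect; native `text-anchor`.
* EPS: `%%BoundingBox`-correct PostScript, y-axis flipped at write
  time. PostScript has no alpha, so fill opacity is pre-blended against
  the background color — correct for ribbons over background, an
  approximation where translucent ribbons overlap each other.
* PDF 1.4: single page, uncompressed content stream, hand-computed
  xref offsets; opacity via ExtGState `ca`/`CA`; text in the built-in
  Helvetica with approximate metrics (0.522 em mean advance) for
  anchoring, since core-font metric tables are not embedded.

Raster output goes through Pillow at `round(canvas·dpi/72)` pixels
(default 300 dpi, JPEG quality 92, BMP uncompressed 24-bit). Curves are
flattened to 24-segment polylines; translucent shapes are drawn on
bounding-box overlays and alpha-composited so overlaps blend correctly.
Text uses Pillow's scalable default font — raster text is therefore not
glyph-identical to the Helvetica of the vector outputs, only positioned
identically. No supersampling is applied; at the default 300 dpi,
edge aliasing is below visual relevance, and raster determinism is
retained.

## Synthetic fixtures

The generator emulates the *shape* of detector output on a two-genome
comparison, not evolutionary realism. Genes are laid end-to-start per
chromosome with exponential intergenic gaps (defaults: mean gene length
2.5 kb, mean gap 8 kb — a gene density of roughly one gene per 10 kb,
typical of compact plant genomes). Blocks pair runs of consecutive
genes on two chromosomes, reversing side b's order for minus blocks;
anchor e-values are written as the literal `0`. The preset
two-genome fixture uses 12 + 10 chromosomes (the rice/sorghum
chromosome counts, used purely as a familiar shape), 40 genes per
chromosome, 30 cross-species blocks of 4–10 anchors, 30 % minus —
small enough that the full 24-file output matrix renders in seconds.
One seeded `numpy` Generator drives everything; no global random state.

What the fixtures do **not** model: nested inversions, tandem arrays,
whole-genome-duplication anchor ratios, overlapping block coordinates
from relaxed detector settings, or annotation noise. Tests passing on
fixtures therefore demonstrate format and geometry correctness, not
robustness to every artifact of real annotations — the validation
policies exist for the latter.

## Numerical choices and edge cases

* Arc closure Σspans + C·g = 2π holds to < 1e-9 (it is exact up to
  float summation); interpolation agrees with an independent oracle to
  1e-12.
* Length-1 chromosomes map every position to the span midpoint rather
  than dividing by zero.
* e-values parse from scientific notation; underflow (`1e-400`) clamps
  to 0, matching the `0` literal detectors print.
* Ties in gene sort order are broken by (start, end, gene_id) so model
  construction is a total order.
* Self-synteny blocks (both sides on one chromosome) are drawn like any
  other ribbon; no special case.
* Unknown control-file keys warn rather than fail, so config files can
  be shared across tool versions; out-of-range values fail naming the
  key.

## Problem sizes

The bundled preset (22 chromosomes, 880 genes, 30 blocks) is the
standard test and demo size; the full 4 × 6 output matrix on it renders
in well under a minute on one CPU, dominated by the three 300-dpi
rasters per plot. Parser round-trip checks run 50 independent seeds of
a 5-chromosome, 110-gene configuration. Layouts are O(genes + anchors)
and have been exercised well beyond these sizes; rendering cost is
dominated by raster pixel count, so very large canvases should lower
`raster_dpi`.

## Known limitations

* One ring, one track: no multi-ring circular tracks, no gene-level
  micro-synteny zoom, no interactivity.
* The dot plot uses base-pair midpoints, not gene ranks; gene-rank
  axes were rejected to keep a single coordinate convention.
* EPS opacity is blended, not composited (above).
* BLAST tabular input is not converted to blocks; run a collinearity
  detector first.
* Raster text glyphs come from Pillow's bundled font, not Helvetica.
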