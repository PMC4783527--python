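# synplot

Publication-quality genome synteny and collinearity figures from
MCScanX-style collinearity output.

Comparative genomics pipelines detect collinear blocks — runs of anchor
gene pairs whose order is conserved between two chromosomal regions —
but most detection tools leave visualization to the user. `synplot`
takes the two files such a pipeline already produces (a collinearity
file of `## Alignment` blocks and a gene annotation giving each gene's
chromosome and 1-based coordinates) and draws the four standard
macrosynteny views:

* **circle** — a circular ideogram: every chromosome is an arc with
  angular span `(2π − C·g)·Lᵢ/ΣL` (C chromosomes, gap angle `g`,
  lengths `L`), and each block is a chord ribbon whose curved edges are
  cubic Béziers pinched toward the center;
* **bar** — stacked horizontal chromosome bars on one global bp→point
  scale, each block painting the same color on both partner bars;
* **dot** — a macrosynteny dot plot: one point per anchor pair at the
  two genes' midpoints on cumulative chromosome axes, colored by block
  orientation (plus/minus);
* **dual** — two facing columns of chromosome bars with quadrilateral
  bands joining each block's extents on a chosen species pair.

Every plot renders to three vector formats (SVG, EPS, PDF — written
deterministically, byte-identical across runs) and three raster formats
(PNG, JPEG, BMP, at any dpi) through one backend-neutral scene graph.
A seeded fixture generator (`synplot.fixtures`) emits valid
collinearity/annotation pairs with known ground truth for testing and
demos.

Intended users: anyone running MCScanX, MCScan, i-ADHoRe or similar
detectors who needs figures for papers without hand-writing Circos
configs. `synplot` visualizes collinearity; it does not detect it.

## Worked example

Generate a desk-scale synthetic two-genome dataset (rice/sorghum-shaped:
12 + 10 chromosomes, 30 cross-species blocks) and draw everything:

```sh
python - <<'EOF'
import synplot
synplot.rice_sorghum_like(seed=1, out_dir="demo")
EOF
synplot --collinearity demo/fixture.collinearity \
        --gff demo/fixture.gene_positions \
        --plot all --format svg --format png \
        --out demo/fig
```

which prints

```
2 genomes, 22 chromosomes, 880 genes; 30 blocks plotted (0 blocks / 0
anchors dropped in validation); 8 file(s) written
```

and writes `demo/fig.circle.svg`, `demo/fig.circle.png`, …,
`demo/fig.dual.png` — 4 plot types × 2 requested formats. The summary
line reports what survived validation: every anchor gene id in the
collinearity file was found in the annotation, so nothing was dropped.
With real data, `--policy drop` tolerates anchors missing from the
annotation (dropped and counted); the default `strict` policy fails
loudly, naming the offending gene and block.

The same run in Python:

```python
import synplot as sp

genes   = sp.parse_gene_positions("demo/fixture.gene_positions")
blocks  = sp.parse_collinearity("demo/fixture.collinearity")
dataset = sp.join_and_validate(sp.build_genome_models(genes), blocks)

cfg    = sp.PlotConfig(plot_type="circle")
layout = sp.compute_layout(dataset, cfg)
scene  = sp.layout_to_scene(layout, cfg)
sp.render(scene, "pdf", "demo/circle.pdf")
```

## Input formats

* **Collinearity**: MCScanX `.collinearity` dialect — `## Alignment
  <id>: score=<s> e_value=<e> N=<n> <chrA>&<chrB> <plus|minus>` headers
  followed by `<id>-<k>: geneA geneB e_value` anchor lines; `#` banner
  lines ignored. Header chromosome tags without zero padding (`os1`)
  are reconciled with annotation ids (`os01`) automatically.
* **Annotation**: either the simplified 4-column gene-position file
  (`chrom  gene  start  end`, tab-separated) or GFF3 (only `gene`
  features; the `ID` attribute is the gene id). Dialect auto-detected.
* **Control file**: optional flat `key=value` lines (`canvas_width=800`,
  `palette=#1F77B4,#FF7F0E`, `ribbon_opacity=0.3`, …); CLI flags
  override file values. See `synplot.PlotConfig` for the full schema
  and defaults.
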