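"""Seeded generator of matching collinearity + annotation file pairs.

Emits the exact dialects the readers accept, together with the in-memory
ground truth they must re-parse to, so every pipeline stage is testable
without external downloads.  Genes are laid end-to-start along each
chromosome with exponential intergenic gaps; blocks pair consecutive gene
runs on two chromosomes (order reversed on side b for minus-orientation
blocks), which is structurally what collinearity detectors report.

The generator is deterministic: one seed-addressed pseudo-random stream,
no global random state, identical bytes for identical parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    AnchorPair,
    GeneRecord,
    GenomeModel,
    SynplotError,
    SyntenyBlock,
    build_genome_models,
)

__all__ = [
    "SpeciesSpec",
    "FixtureParams",
    "FixtureTruth",
    "GenerationError",
    "generate",
    "rice_sorghum_like",
]


class GenerationError(SynplotError):
    """Parameters demand structures that cannot be generated."""


@dataclass(frozen=True)
class SpeciesSpec:
    tag: str
    n_chromosomes: int
    genes_per_chromosome: int
    mean_gene_length_bp: float = 2500.0
    mean_intergenic_bp: float = 8000.0


@dataclass(frozen=True)
class FixtureParams:
    seed: int
    species: tuple[SpeciesSpec, ...]
    n_blocks: int = 10
    anchors_per_block: tuple[int, int] = (3, 8)  # inclusive range
    p_minus: float = 0.3
    p_cross_species: float = 1.0

    def __post_init__(self) -> None:
        if not self.species:
            raise GenerationError("at least one species required")
        for sp in self.species:
            if min(sp.n_chromosomes, sp.genes_per_chromosome) < 1:
                raise GenerationError("counts must be >= 1")
        if self.n_blocks < 1:
            raise GenerationError("n_blocks must be >= 1")
        lo, hi = self.anchors_per_block
        if not (1 <= lo <= hi):
            raise GenerationError("anchors_per_block must be 1 <= lo <= hi")
        for p in (self.p_minus, self.p_cross_species):
            if not 0.0 <= p <= 1.0:
                raise GenerationError("probabilities must be in [0,1]")


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth plus the emitted file texts (and paths, if written)."""

    params: FixtureParams
    genomes: tuple[GenomeModel, ...]
    blocks: tuple[SyntenyBlock, ...]
    anchor_histogram: dict[int, int]
    annotation_text: str
    collinearity_text: str
    annotation_path: Path | None = None
    collinearity_path: Path | None = None
    genes: tuple[GeneRecord, ...] = field(default=(), repr=False)


def _header_tag(chrom_id: str, species_tag: str) -> str:
    """Header spelling of a chromosome id: zero padding dropped
    ('os01' -> 'os1'), as MCScanX block headers print them."""
    suffix = chrom_id[len(species_tag):]
    if suffix.isdigit():
        return f"{species_tag}{int(suffix)}"
    return chrom_id


def generate(params: FixtureParams, out_dir: str | Path | None = None) -> FixtureTruth:
    """Generate a matched annotation + collinearity fixture.

    If ``out_dir`` is given, writes ``fixture.gene_positions`` (simplified
    4-column annotation) and ``fixture.collinearity`` there.
    """
    rng = np.random.default_rng(params.seed)

    genes: list[GeneRecord] = []
    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for sp in params.species:
        for ci in range(1, sp.n_chromosomes + 1):
            chrom_id = f"{sp.tag}{ci:02d}"
            cursor = 0
            chrom_genes = []
            for gi in range(1, sp.genes_per_chromosome + 1):
                gap = 1 + int(rng.exponential(sp.mean_intergenic_bp))
                length = 1 + int(rng.exponential(sp.mean_gene_length_bp))
                start = cursor + gap
                end = start + length
                cursor = end
                g = GeneRecord(f"{chrom_id}g{gi:04d}", chrom_id, start, end)
                chrom_genes.append(g)
            genes.extend(chrom_genes)
            genes_by_chrom[chrom_id] = chrom_genes

    blocks: list[SyntenyBlock] = []
    lo, hi = params.anchors_per_block
    tags = [sp.tag for sp in params.species]
    chroms_by_tag = {
        sp.tag: [f"{sp.tag}{ci:02d}" for ci in range(1, sp.n_chromosomes + 1)]
        for sp in params.species
    }
    gpc = {sp.tag: sp.genes_per_chromosome for sp in params.species}

    for bid in range(params.n_blocks):
        n = int(rng.integers(lo, hi + 1))
        cross = len(tags) >= 2 and rng.random() < params.p_cross_species
        if cross:
            ia, ib = rng.choice(len(tags), size=2, replace=False)
            tag_a, tag_b = tags[ia], tags[ib]
        else:
            tag_a = tag_b = tags[int(rng.integers(len(tags)))]
        if n > min(gpc[tag_a], gpc[tag_b]):
            raise GenerationError(
                f"block of {n} anchors needs more genes than a chromosome "
                f"holds (genes_per_chromosome too small)"
            )
        chrom_a = chroms_by_tag[tag_a][int(rng.integers(len(chroms_by_tag[tag_a])))]
        chrom_b = chroms_by_tag[tag_b][int(rng.integers(len(chroms_by_tag[tag_b])))]
        ga = genes_by_chrom[chrom_a]
        gb = genes_by_chrom[chrom_b]
        sa = int(rng.integers(0, len(ga) - n + 1))
        sb = int(rng.integers(0, len(gb) - n + 1))
        minus = rng.random() < params.p_minus
        anchors = tuple(
            AnchorPair(
                gene_a=ga[sa + k].gene_id,
                gene_b=gb[sb + (n - 1 - k if minus else k)].gene_id,
                e_value=0.0,
                index_in_block=k,
            )
            for k in range(n)
        )
        blocks.append(
            SyntenyBlock(
                block_id=bid,
                score=50.0 * n,
                e_value=0.0,
                n_declared=n,
                chrom_a=chrom_a,
                chrom_b=chrom_b,
                orientation="minus" if minus else "plus",
                anchors=anchors,
            )
        )

    genomes = tuple(build_genome_models(genes))

    ann_lines = [
        f"{g.chrom_id}\t{g.gene_id}\t{g.start}\t{g.end}"
        for gm in genomes for cm in gm.chromosomes for g in cm.genes
    ]
    annotation_text = "\n".join(ann_lines) + "\n"

    col_lines = [
        "############### Parameters ###############",
        "# MATCH_SCORE: 50",
        "# E_VALUE: 1e-05",
        "############### Statistics ###############",
        f"# Number of collinear blocks: {len(blocks)}",
    ]
    tag_of = {c: gm.species_tag for gm in genomes for c in
              (cm.chrom_id for cm in gm.chromosomes)}
    for blk in blocks:
        ha = _header_tag(blk.chrom_a, tag_of[blk.chrom_a])
        hb = _header_tag(blk.chrom_b, tag_of[blk.chrom_b])
        col_lines.append(
            f"## Alignment {blk.block_id}: score={blk.score:.1f} "
            f"e_value=0 N={blk.n_declared} {ha}&{hb} {blk.orientation}"
        )
        for a in blk.anchors:
            col_lines.append(
                f"{blk.block_id:3d}-{a.index_in_block:3d}:\t"
                f"{a.gene_a}\t{a.gene_b}\t      0"
            )
    collinearity_text = "\n".join(col_lines) + "\n"

    histogram: dict[int, int] = {}
    for blk in blocks:
        histogram[len(blk.anchors)] = histogram.get(len(blk.anchors), 0) + 1

    ann_path = col_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ann_path = out_dir / "fixture.gene_positions"
        col_path = out_dir / "fixture.collinearity"
        ann_path.write_text(annotation_text, encoding="utf-8")
        col_path.write_text(collinearity_text, encoding="utf-8")

    return FixtureTruth(
        params=params,
        genomes=genomes,
        blocks=tuple(blocks),
        anchor_histogram=histogram,
        annotation_text=annotation_text,
        collinearity_text=collinearity_text,
        annotation_path=ann_path,
        collinearity_path=col_path,
        genes=tuple(genes),
    )


def rice_sorghum_like(
    seed: int = 1, out_dir: str | Path | None = None
) -> FixtureTruth:
    """Desk-scale stand-in shaped like a rice/sorghum comparison.

    Two species tagged ``os`` (12 chromosomes) and ``sb`` (10), with
    cross-species blocks only.  The chromosome counts are common
    biological knowledge used purely as a fixture shape; the coordinates
    and blocks are synthetic, NOT real data.
    """
    params = FixtureParams(
        seed=seed,
        species=(
            SpeciesSpec("os", 12, 40),
            SpeciesSpec("sb", 10, 40),
        ),
        n_blocks=30,
        anchors_per_block=(4, 10),
        p_minus=0.3,
        p_cross_species=1.0,
    )
    return generate(params, out_dir=out_dir)
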