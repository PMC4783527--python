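"""Domain model for genome synteny/collinearity visualization.

The model joins two inputs: a gene annotation (which genes sit where on
which chromosome) and a set of collinear blocks (runs of anchor gene
pairs reported by synteny-detection tools such as MCScanX).  All genomic
coordinates are 1-based and inclusive, following the GFF convention;
conversion to canvas coordinates happens only in :mod:`synplot.layout`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "GeneRecord",
    "ChromosomeModel",
    "GenomeModel",
    "AnchorPair",
    "SyntenyBlock",
    "SyntenyDataset",
    "ValidationReport",
    "SynplotError",
    "ModelError",
    "ValidationError",
    "build_genome_models",
    "join_and_validate",
    "natural_key",
    "normalize_chrom_tag",
]


class SynplotError(Exception):
    """Base class for all errors raised by this package."""


class ModelError(SynplotError):
    """Malformed or inconsistent in-memory model input."""


class ValidationError(SynplotError):
    """Annotation and collinearity data cannot be reconciled."""


_SPECIES_PREFIX_RE = re.compile(r"^[A-Za-z]+")
_NATURAL_CHUNK_RE = re.compile(r"(\d+)")


def natural_key(s: str) -> tuple:
    """Sort key treating digit runs numerically: 'os2' < 'os10'."""
    return tuple(
        int(chunk) if chunk.isdigit() else chunk
        for chunk in _NATURAL_CHUNK_RE.split(s)
    )


def normalize_chrom_tag(tag: str) -> tuple[str, ...]:
    """Canonical identity of a chromosome tag: (species prefix, int suffix).

    MCScanX block headers drop zero padding ('os1'), while annotations
    usually keep it ('os01'); both normalize to ('os', 1).  Tags without a
    trailing integer normalize to themselves.
    """
    m = re.fullmatch(r"([A-Za-z_.-]*?)(\d+)", tag)
    if m:
        return (m.group(1).lower(), int(m.group(2)))
    return (tag.lower(),)


@dataclass(frozen=True)
class GeneRecord:
    """One gene: id, chromosome, 1-based inclusive extent, optional strand."""

    gene_id: str
    chrom_id: str
    start: int
    end: int
    strand: str = "unknown"  # one of {"+", "-", "unknown"}

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ModelError(
                f"gene {self.gene_id!r}: require 1 <= start <= end, "
                f"got start={self.start} end={self.end}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ModelError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class ChromosomeModel:
    chrom_id: str
    species_tag: str
    length_bp: int
    genes: tuple[GeneRecord, ...]  # sorted by start

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ModelError(f"chromosome {self.chrom_id!r}: length_bp must be > 0")
        if self.genes and self.length_bp < max(g.end for g in self.genes):
            raise ModelError(
                f"chromosome {self.chrom_id!r}: length_bp {self.length_bp} "
                f"shorter than max gene end"
            )
        for g in self.genes:
            if g.chrom_id != self.chrom_id:
                raise ModelError(
                    f"gene {g.gene_id!r} on {g.chrom_id!r} placed in "
                    f"chromosome {self.chrom_id!r}"
                )


@dataclass(frozen=True)
class GenomeModel:
    species_tag: str
    chromosomes: tuple[ChromosomeModel, ...]
    display_name: str = ""

    def __post_init__(self) -> None:
        ids = [c.chrom_id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ModelError(f"genome {self.species_tag!r}: duplicate chromosome ids")


@dataclass(frozen=True)
class AnchorPair:
    """One collinear gene pair inside a block."""

    gene_a: str
    gene_b: str
    e_value: float = 0.0
    index_in_block: int = 0


@dataclass(frozen=True)
class SyntenyBlock:
    """One '## Alignment' unit: a run of anchors joining two chromosomes."""

    block_id: int
    score: float
    e_value: float
    n_declared: int
    chrom_a: str
    chrom_b: str
    orientation: str  # "plus" or "minus"
    anchors: tuple[AnchorPair, ...]

    def __post_init__(self) -> None:
        if self.orientation not in ("plus", "minus"):
            raise ModelError(
                f"block {self.block_id}: orientation must be plus/minus, "
                f"got {self.orientation!r}"
            )


@dataclass(frozen=True)
class ValidationReport:
    anchors_dropped: int = 0
    blocks_dropped: int = 0
    chrom_tags_rewritten: int = 0


@dataclass(frozen=True)
class SyntenyDataset:
    """Annotation joined with collinearity; every anchor gene resolvable."""

    genomes: tuple[GenomeModel, ...]
    blocks: tuple[SyntenyBlock, ...]
    gene_index: dict[str, tuple[GenomeModel, ChromosomeModel, GeneRecord]] = field(
        repr=False, default_factory=dict
    )
    report: ValidationReport = field(default_factory=ValidationReport)

    @property
    def chromosomes(self) -> list[ChromosomeModel]:
        """All chromosomes in canonical drawing order (genomes by tag)."""
        return [c for g in self.genomes for c in g.chromosomes]

    def genome(self, species_tag: str) -> GenomeModel:
        for g in self.genomes:
            if g.species_tag == species_tag:
                return g
        raise KeyError(f"unknown species tag {species_tag!r}")

    def chromosome(self, chrom_id: str) -> ChromosomeModel:
        for g in self.genomes:
            for c in g.chromosomes:
                if c.chrom_id == chrom_id:
                    return c
        raise KeyError(f"unknown chromosome {chrom_id!r}")


def _species_tag(chrom_id: str, line_hint: str | None = None) -> str:
    m = _SPECIES_PREFIX_RE.match(chrom_id)
    if not m:
        where = f" ({line_hint})" if line_hint else ""
        raise ModelError(
            f"chromosome id {chrom_id!r} has no alphabetic species prefix{where}"
        )
    return m.group(0)


def build_genome_models(
    genes: list[GeneRecord],
    length_overrides: dict[str, int] | None = None,
    species_regex: str | None = None,
) -> list[GenomeModel]:
    """Group genes into chromosomes and genomes.

    The species tag is the leading alphabetic run of each chromosome id
    (override with ``species_regex``, whose first group is the tag).
    Chromosome extent is the maximum gene end unless an explicit override
    is given; the annotation is the only source of chromosome sizes here.
    Genomes sort by species tag, chromosomes natural-sort within a genome,
    so the result is invariant under permutation of the input gene list.
    """
    if not genes:
        raise ModelError("no genes: annotation produced an empty gene list")
    overrides = dict(length_overrides or {})
    tag_re = re.compile(species_regex) if species_regex else None

    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom_id, []).append(g)

    by_species: dict[str, list[ChromosomeModel]] = {}
    for chrom_id in sorted(by_chrom, key=natural_key):
        cg = sorted(by_chrom[chrom_id], key=lambda g: (g.start, g.end, g.gene_id))
        if tag_re is not None:
            m = tag_re.match(chrom_id)
            if not m:
                raise ModelError(
                    f"chromosome id {chrom_id!r} does not match species regex"
                )
            tag = m.group(1) if m.groups() else m.group(0)
        else:
            tag = _species_tag(chrom_id, line_hint=f"gene {cg[0].gene_id!r}")
        length = overrides.get(chrom_id, max(g.end for g in cg))
        by_species.setdefault(tag, []).append(
            ChromosomeModel(chrom_id, tag, length, tuple(cg))
        )

    return [
        GenomeModel(tag, tuple(by_species[tag]), display_name=tag)
        for tag in sorted(by_species)
    ]


def join_and_validate(
    genomes: list[GenomeModel],
    blocks: list[SyntenyBlock],
    policy: str = "strict",
) -> SyntenyDataset:
    """Join annotation with collinearity into a validated dataset.

    ``strict`` raises on any anchor gene missing from the annotation or on
    a block header chromosome tag that disagrees with where its anchor
    genes actually sit.  ``drop`` removes offending anchors, removes blocks
    left with fewer than two anchors, rewrites disagreeing header tags from
    the annotation, and counts everything in the returned report.
    """
    if policy not in ("strict", "drop"):
        raise ValueError(f"policy must be 'strict' or 'drop', got {policy!r}")

    gene_index: dict[str, tuple[GenomeModel, ChromosomeModel, GeneRecord]] = {}
    for gm in genomes:
        for cm in gm.chromosomes:
            for g in cm.genes:
                gene_index[g.gene_id] = (gm, cm, g)

    anchors_dropped = 0
    blocks_dropped = 0
    tags_rewritten = 0
    kept_blocks: list[SyntenyBlock] = []

    for blk in blocks:
        kept: list[AnchorPair] = []
        chrom_a_seen: str | None = None
        chrom_b_seen: str | None = None
        for anchor in blk.anchors:
            missing = [g for g in (anchor.gene_a, anchor.gene_b) if g not in gene_index]
            if missing:
                if policy == "strict":
                    raise ValidationError(
                        f"block {blk.block_id}: anchor gene {missing[0]!r} "
                        f"not found in the annotation"
                    )
                anchors_dropped += 1
                continue
            ca = gene_index[anchor.gene_a][1].chrom_id
            cb = gene_index[anchor.gene_b][1].chrom_id
            if chrom_a_seen is None:
                chrom_a_seen, chrom_b_seen = ca, cb
            elif (ca, cb) != (chrom_a_seen, chrom_b_seen):
                if policy == "strict":
                    raise ValidationError(
                        f"block {blk.block_id}: anchor "
                        f"({anchor.gene_a!r}, {anchor.gene_b!r}) sits on "
                        f"({ca}, {cb}) but earlier anchors on "
                        f"({chrom_a_seen}, {chrom_b_seen})"
                    )
                anchors_dropped += 1
                continue
            kept.append(anchor)

        if policy == "drop" and len(kept) < 2:
            blocks_dropped += 1
            continue

        # Reconcile header chromosome tags with the annotation.  MCScanX
        # headers drop zero padding, so 'os1' vs 'os01' is mere spelling;
        # a genuinely different chromosome is a validation failure.
        new_blk = blk
        for attr, seen in (("chrom_a", chrom_a_seen), ("chrom_b", chrom_b_seen)):
            declared = getattr(blk, attr)
            if seen is None or declared == seen:
                continue
            if normalize_chrom_tag(declared) == normalize_chrom_tag(seen):
                new_blk = replace(new_blk, **{attr: seen})
            else:
                if policy == "strict":
                    raise ValidationError(
                        f"block {blk.block_id}: header names {declared!r} but "
                        f"anchor genes sit on {seen!r}"
                    )
                new_blk = replace(new_blk, **{attr: seen})
                tags_rewritten += 1
        if new_blk.anchors != tuple(kept):
            new_blk = replace(new_blk, anchors=tuple(kept))
        kept_blocks.append(new_blk)

    return SyntenyDataset(
        genomes=tuple(genomes),
        blocks=tuple(kept_blocks),
        gene_index=gene_index,
        report=ValidationReport(anchors_dropped, blocks_dropped, tags_rewritten),
    )
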