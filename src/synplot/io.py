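"""Readers for the three user inputs.

1. Collinearity file — the MCScanX ``.collinearity`` dialect: block
   headers of the form ``## Alignment 0: score=9171.0 e_value=0 N=2
   os1&sb1 plus`` followed by one anchor gene-pair line per collinear
   pair, plus a leading '#' parameter banner that is ignored.
2. Gene annotation — either the simplified 4-column gene-position file
   MCScanX distributes (``chrom  gene_id  start  end``) or standard GFF3
   (only ``gene`` features are used).  The dialect is auto-detected.
3. Control file — flat ``key=value`` lines configuring the plot.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, fields
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping

from .model import AnchorPair, GeneRecord, SynplotError, SyntenyBlock

__all__ = [
    "PlotConfig",
    "FormatError",
    "ConfigError",
    "PLOT_TYPES",
    "OUT_FORMATS",
    "DEFAULT_PALETTE",
    "parse_collinearity",
    "parse_gene_positions",
    "detect_annotation_dialect",
    "parse_config",
]

log = logging.getLogger("synplot")


class FormatError(SynplotError):
    """An input file does not match its expected grammar."""


class ConfigError(SynplotError):
    """A control-file value is unknown-typed or out of range."""


PLOT_TYPES = ("circle", "bar", "dot", "dual")
OUT_FORMATS = ("svg", "eps", "pdf", "png", "jpeg", "bmp")

# 20-color qualitative palette (colorbrewer-like, high mutual contrast),
# cycled by chromosome or block index.
DEFAULT_PALETTE = (
    "#1F77B4", "#FF7F0E", "#2CA02C", "#D62728", "#9467BD",
    "#8C564B", "#E377C2", "#7F7F7F", "#BCBD22", "#17BECF",
    "#AEC7E8", "#FFBB78", "#98DF8A", "#FF9896", "#C5B0D5",
    "#C49C94", "#F7B6D2", "#C7C7C7", "#DBDB8D", "#9EDAE5",
)

_HEX_COLOR_RE = re.compile(r"^#[0-9A-Fa-f]{6}$")


@dataclass
class PlotConfig:
    """Control-file parameter set.

    ``canvas_width``/``canvas_height`` default to None, meaning the
    per-plot-type defaults: 1000x1000 pt for circle and dot, 1000x700 pt
    for bar and dual synteny.
    """

    plot_type: str = "circle"
    out_format: str = "svg"
    canvas_width: float | None = None
    canvas_height: float | None = None
    margin: float = 40.0
    gap_angle: float = math.radians(2.0)
    palette: tuple[str, ...] = DEFAULT_PALETTE
    ribbon_opacity: float = 0.45
    ribbon_pinch: float = 0.0  # 0 = cubic control points at circle center
    dual_pair: tuple[str, str] | None = None
    label_font_size: float = 12.0
    min_block_anchors: int = 2
    raster_dpi: int = 300
    chrom_length_overrides: dict[str, int] = field(default_factory=dict)
    validation_policy: str = "strict"
    species_regex: str | None = None
    background: str = "#FFFFFF"

    def __post_init__(self) -> None:
        self.palette = tuple(self.palette)
        if self.dual_pair is not None:
            self.dual_pair = tuple(self.dual_pair)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        if self.plot_type not in PLOT_TYPES:
            raise ConfigError(
                f"plot_type must be one of {'/'.join(PLOT_TYPES)}, "
                f"got {self.plot_type!r}"
            )
        if self.out_format not in OUT_FORMATS:
            raise ConfigError(
                f"out_format must be one of {'/'.join(OUT_FORMATS)}, "
                f"got {self.out_format!r}"
            )
        for key in ("canvas_width", "canvas_height"):
            v = getattr(self, key)
            if v is not None and v <= 0:
                raise ConfigError(f"{key} must be > 0")
        if self.margin < 0:
            raise ConfigError("margin must be >= 0")
        if self.gap_angle < 0:
            raise ConfigError("gap_angle must be >= 0")
        if not 0.0 <= self.ribbon_opacity <= 1.0:
            raise ConfigError("ribbon_opacity must be in [0,1]")
        if not 0.0 <= self.ribbon_pinch <= 1.0:
            raise ConfigError("ribbon_pinch must be in [0,1]")
        if self.min_block_anchors < 2:
            raise ConfigError("min_block_anchors must be >= 2")
        if self.raster_dpi <= 0:
            raise ConfigError("raster_dpi must be > 0")
        if self.label_font_size <= 0:
            raise ConfigError("label_font_size must be > 0")
        if self.validation_policy not in ("strict", "drop"):
            raise ConfigError("validation_policy must be 'strict' or 'drop'")
        if not self.palette:
            raise ConfigError("palette must list at least one color")
        for c in (*self.palette, self.background):
            if not _HEX_COLOR_RE.match(c):
                raise ConfigError(f"color {c!r} is not #RRGGBB")

    def resolved_canvas(self) -> tuple[float, float]:
        """Canvas (width, height) in points, applying per-plot defaults."""
        if self.plot_type in ("circle", "dot"):
            dw, dh = 1000.0, 1000.0
        else:
            dw, dh = 1000.0, 700.0
        w = self.canvas_width if self.canvas_width is not None else dw
        h = self.canvas_height if self.canvas_height is not None else dh
        return float(w), float(h)

    def color(self, i: int) -> str:
        return self.palette[i % len(self.palette)]


# --------------------------------------------------------------------------
# Collinearity (MCScanX dialect)
# --------------------------------------------------------------------------

_HEADER_RE = re.compile(
    r"^##\s*Alignment\s+(\d+):\s*"
    r"score=([0-9.eE+-]+)\s+"
    r"e_value=([0-9.eE+-]+)\s+"
    r"N=(\d+)\s+"
    r"(\S+)&(\S+)\s+"
    r"(plus|minus)\s*$"
)
# e.g. "  0-  0:\tOs01g0100100\tSb01g000200\t  0" — padding varies.
_ANCHOR_RE = re.compile(
    r"^\s*(\d+)-\s*(\d+):\s+(\S+)\s+(\S+)\s+(\S+)\s*$"
)


def _parse_evalue(token: str, where: str) -> float:
    try:
        v = float(token)
    except ValueError:
        raise FormatError(f"{where}: unparsable e_value {token!r}") from None
    # underflowed scientific notation ('1e-400') comes back 0.0 already;
    # clamp tiny negatives from sloppy producers
    return max(v, 0.0)


def parse_collinearity(path: str | PathLike) -> list[SyntenyBlock]:
    """Parse an MCScanX-style collinearity file into blocks, in file order."""
    path = Path(path)
    blocks: list[SyntenyBlock] = []
    current: dict | None = None
    current_anchors: list[AnchorPair] = []

    def finish() -> None:
        nonlocal current, current_anchors
        if current is None:
            return
        if len(current_anchors) != current["n"]:
            raise FormatError(
                f"{path.name}: block {current['id']}: declared "
                f"{current['n']} anchors, found {len(current_anchors)}"
            )
        blocks.append(
            SyntenyBlock(
                block_id=current["id"],
                score=current["score"],
                e_value=current["e"],
                n_declared=current["n"],
                chrom_a=current["ca"],
                chrom_b=current["cb"],
                orientation=current["orient"],
                anchors=tuple(current_anchors),
            )
        )
        current, current_anchors = None, []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            m = _HEADER_RE.match(line)
            if m:
                finish()
                current = {
                    "id": int(m.group(1)),
                    "score": float(m.group(2)),
                    "e": _parse_evalue(m.group(3), f"{path.name}:{lineno}"),
                    "n": int(m.group(4)),
                    "ca": m.group(5),
                    "cb": m.group(6),
                    "orient": m.group(7),
                }
                continue
            if line.lstrip().startswith("#"):
                if re.match(r"^##\s*Alignment\b", line.lstrip()):
                    raise FormatError(
                        f"{path.name}:{lineno}: unparsable block header: {line!r}"
                    )
                continue  # parameter banner / commentary
            m = _ANCHOR_RE.match(line)
            if m is None:
                raise FormatError(
                    f"{path.name}:{lineno}: unrecognized line: {line!r}"
                )
            if current is None:
                raise FormatError(
                    f"{path.name}:{lineno}: anchor line before any "
                    f"'## Alignment' header"
                )
            bid, idx = int(m.group(1)), int(m.group(2))
            if bid != current["id"]:
                raise FormatError(
                    f"{path.name}:{lineno}: anchor labeled block {bid} "
                    f"inside block {current['id']}"
                )
            current_anchors.append(
                AnchorPair(
                    gene_a=m.group(3),
                    gene_b=m.group(4),
                    e_value=_parse_evalue(m.group(5), f"{path.name}:{lineno}"),
                    index_in_block=idx,
                )
            )
    finish()
    return blocks


# --------------------------------------------------------------------------
# Gene annotation (simplified 4-column or GFF3)
# --------------------------------------------------------------------------


def detect_annotation_dialect(first_data_lines: Iterable[str]) -> str:
    """Classify annotation lines as 'simplified' or 'gff3'.

    Simplified: 4 tab-separated fields with integer fields 3-4.
    GFF3: >= 8 tab-separated fields.
    """
    votes: set[str] = set()
    n = 0
    for line in first_data_lines:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) == 4 and cols[2].strip().isdigit() and cols[3].strip().isdigit():
            votes.add("simplified")
        elif len(cols) >= 8:
            votes.add("gff3")
        else:
            raise FormatError(
                f"unrecognized annotation format (line: {line[:80]!r})"
            )
        n += 1
    if n == 0:
        raise FormatError("unrecognized annotation format: no data lines")
    if len(votes) != 1:
        raise FormatError("unrecognized annotation format: mixed dialects")
    return votes.pop()


_GFF_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def parse_gene_positions(path: str | PathLike) -> list[GeneRecord]:
    """Parse a gene annotation file (auto-detected dialect) into records."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    sample = [l for l in lines if l.strip() and not l.startswith("#")][:50]
    dialect = detect_annotation_dialect(sample)

    genes: list[GeneRecord] = []
    seen: dict[str, int] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if dialect == "simplified":
            if len(cols) != 4:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 4 tab-separated columns"
                )
            chrom, gid = cols[0].strip(), cols[1].strip()
            start_s, end_s, strand = cols[2], cols[3], "unknown"
        else:
            if len(cols) < 8:
                raise FormatError(
                    f"{path.name}:{lineno}: expected >= 8 GFF3 columns"
                )
            if cols[2].strip() != "gene":
                continue
            chrom = cols[0].strip()
            start_s, end_s = cols[3], cols[4]
            strand = cols[6].strip()
            if strand not in ("+", "-"):
                strand = "unknown"
            attrs = cols[8] if len(cols) > 8 else ""
            m = _GFF_ID_RE.search(attrs)
            if not m:
                raise FormatError(
                    f"{path.name}:{lineno}: gene feature lacks an ID attribute"
                )
            gid = m.group(1).strip()
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(
                f"{path.name}:{lineno}: non-integer coordinates "
                f"{start_s!r}/{end_s!r}"
            ) from None
        if start > end:
            raise FormatError(f"{path.name}:{lineno}: start {start} > end {end}")
        if gid in seen:
            raise FormatError(
                f"{path.name}:{lineno}: duplicate gene id {gid!r} "
                f"(first seen line {seen[gid]})"
            )
        seen[gid] = lineno
        genes.append(GeneRecord(gid, chrom, start, end, strand))
    return genes


# --------------------------------------------------------------------------
# Control file
# --------------------------------------------------------------------------

_CONFIG_FIELDS = {f.name: f for f in fields(PlotConfig)}


def _coerce(key: str, value):
    """Coerce a raw control-file string to the field's type."""
    if not isinstance(value, str):
        return value
    v = value.strip()
    if key in ("canvas_width", "canvas_height"):
        return float(v)
    if key in ("margin", "gap_angle", "ribbon_opacity", "ribbon_pinch",
               "label_font_size"):
        return float(v)
    if key in ("min_block_anchors", "raster_dpi"):
        return int(v)
    if key == "palette":
        return tuple(c.strip() for c in v.split(",") if c.strip())
    if key == "dual_pair":
        parts = tuple(p.strip() for p in v.split(",") if p.strip())
        if len(parts) != 2:
            raise ConfigError("dual_pair must be two species tags 'a,b'")
        return parts
    if key == "chrom_length_overrides":
        out: dict[str, int] = {}
        for item in v.split(","):
            if not item.strip():
                continue
            chrom, _, bp = item.partition(":")
            if not bp:
                raise ConfigError(
                    "chrom_length_overrides entries must be 'chrom:bp'"
                )
            out[chrom.strip()] = int(bp)
        return out
    return v


def parse_config(source: str | PathLike | Mapping | None) -> PlotConfig:
    """Build a PlotConfig from a key=value control file or a mapping.

    Unknown keys warn and are ignored; missing keys take the documented
    defaults; values outside their valid range raise :class:`ConfigError`
    naming the key.  ``None`` yields all defaults.
    """
    if source is None:
        return PlotConfig()
    if isinstance(source, Mapping):
        items = dict(source)
    else:
        items = {}
        path = Path(source)
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                # '#' opens a comment only at line start or after whitespace,
                # so #RRGGBB color values survive
                line = re.sub(r"(?:^|\s)#.*$", "", raw).strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(
                        f"{path.name}:{lineno}: expected key=value, got {line!r}"
                    )
                key, _, value = line.partition("=")
                items[key.strip()] = value.strip()

    kwargs = {}
    for key, value in items.items():
        if key not in _CONFIG_FIELDS:
            log.warning("control file: unknown key %r ignored", key)
            continue
        try:
            kwargs[key] = _coerce(key, value)
        except ConfigError:
            raise
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad value for {key!r}: {exc}") from None
    return PlotConfig(**kwargs)
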