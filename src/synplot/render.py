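"""Backend-neutral scene graph and the multi-format adaptor.

A :class:`Scene` is an ordered painter's list of primitives (arc bands,
chord ribbons, polygons, segments, markers, text) in canvas coordinates
(origin top-left, y down, points).  Writers serialize one scene to any of
six formats — vector SVG/EPS/PDF and raster PNG/JPEG/BMP — without the
plotting code knowing which.  Vector output is deterministic: no
timestamps, generator versions, or randomized element ids, so identical
scenes produce byte-identical files.

Each primitive carries either a fill or a stroke (never both), so every
primitive maps to exactly one drawable element per backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from os import PathLike
from pathlib import Path

from PIL import Image, ImageDraw, ImageFont

from .io import OUT_FORMATS, PlotConfig
from .layout import (
    ArcSpan,
    BandMark,
    DotMark,
    IntervalMark,
    Label,
    LayoutResult,
    LinearSpan,
    RibbonGeometry,
    SegmentMark,
    polar_point,
)
from .model import SynplotError

__all__ = [
    "Style",
    "Primitive",
    "Scene",
    "RenderError",
    "layout_to_scene",
    "render",
    "render_all_formats",
    "FORMAT_SIGNATURES",
]

JPEG_QUALITY = 92
BAR_FILL = "#E3E3E3"
FONT_FAMILY = "Helvetica"
# mean advance width of Helvetica at 1000 units/em, used where a backend
# cannot measure strings (PDF text anchoring, raster fallback)
APPROX_CHAR_WIDTH = 0.522

FORMAT_SIGNATURES: dict[str, tuple[bytes, ...]] = {
    "svg": (b"<?xml", b"<svg"),
    "eps": (b"%!PS",),
    "pdf": (b"%PDF",),
    "png": (b"\x89PNG\r\n\x1a\n",),
    "jpeg": (b"\xff\xd8",),
    "bmp": (b"BM",),
}


class RenderError(SynplotError):
    """A scene could not be serialized to the requested format."""


@dataclass(frozen=True)
class Style:
    fill: str | None = None
    stroke: str | None = None
    stroke_width: float = 1.0
    opacity: float = 1.0
    font_size: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.opacity <= 1.0:
            raise RenderError("opacity must be in [0,1]")


@dataclass(frozen=True)
class Primitive:
    """One drawing instruction.

    geometry by kind:
      arc_band      (cx, cy, r_in, r_out, t1, t2)
      cubic_ribbon  (cx, cy, r, ta1, ta2, tb1, tb2, c1a, c1b, c2a, c2b)
      polygon       ((x, y), ...)
      segment       ((x0, y0), (x1, y1))
      circle_marker ((cx, cy), r)
      text          (x, y, string, rotation_deg, anchor)
    """

    kind: str
    geometry: tuple
    style: Style


@dataclass(frozen=True)
class Scene:
    width: float
    height: float
    background: str
    primitives: tuple[Primitive, ...]


# --------------------------------------------------------------------------
# Path construction (shared by all writers)
# --------------------------------------------------------------------------


def _arc_cubics(cx, cy, r, t1, t2):
    """Cubic Bezier segments approximating the arc t1 -> t2.

    Works in the ideogram convention (0 at 12 o'clock, clockwise); the
    tangent of p(t) = (cx + r sin t, cy - r cos t) is (r cos t, r sin t).
    """
    segs = []
    n = max(1, math.ceil(abs(t2 - t1) / (math.pi / 2.0)))
    step = (t2 - t1) / n
    for i in range(n):
        a = t1 + i * step
        b = a + step
        k = (4.0 / 3.0) * math.tan((b - a) / 4.0)
        pa = polar_point((cx, cy), r, a)
        pb = polar_point((cx, cy), r, b)
        ta = (r * math.cos(a), r * math.sin(a))
        tb = (r * math.cos(b), r * math.sin(b))
        segs.append((
            (pa[0] + k * ta[0], pa[1] + k * ta[1]),
            (pb[0] - k * tb[0], pb[1] - k * tb[1]),
            pb,
        ))
    return segs


def primitive_path(prim: Primitive):
    """Path commands for a shape primitive: M/L/C/Z tuples."""
    g = prim.geometry
    if prim.kind == "arc_band":
        cx, cy, r_in, r_out, t1, t2 = g
        cmds = [("M", polar_point((cx, cy), r_out, t1))]
        for c1, c2, p in _arc_cubics(cx, cy, r_out, t1, t2):
            cmds.append(("C", c1, c2, p))
        cmds.append(("L", polar_point((cx, cy), r_in, t2)))
        for c1, c2, p in _arc_cubics(cx, cy, r_in, t2, t1):
            cmds.append(("C", c1, c2, p))
        cmds.append(("Z",))
        return cmds
    if prim.kind == "cubic_ribbon":
        cx, cy, r, ta1, ta2, tb1, tb2, c1a, c1b, c2a, c2b = g
        p3 = polar_point((cx, cy), r, tb1)
        p1 = polar_point((cx, cy), r, ta1)
        cmds = [("M", p1)]
        for c1, c2, p in _arc_cubics(cx, cy, r, ta1, ta2):
            cmds.append(("C", c1, c2, p))
        cmds.append(("C", c1a, c1b, p3))
        for c1, c2, p in _arc_cubics(cx, cy, r, tb1, tb2):
            cmds.append(("C", c1, c2, p))
        cmds.append(("C", c2a, c2b, p1))
        cmds.append(("Z",))
        return cmds
    if prim.kind == "polygon":
        cmds = [("M", g[0])]
        cmds.extend(("L", p) for p in g[1:])
        cmds.append(("Z",))
        return cmds
    if prim.kind == "segment":
        return [("M", g[0]), ("L", g[1])]
    raise RenderError(f"no path for primitive kind {prim.kind!r}")


def _flatten(cmds, n: int = 24):
    """Flatten path commands to a polyline point list (for rasterizing)."""
    pts: list[tuple[float, float]] = []
    start: tuple[float, float] | None = None
    for cmd in cmds:
        if cmd[0] == "M":
            start = cmd[1]
            pts.append(cmd[1])
        elif cmd[0] == "L":
            pts.append(cmd[1])
        elif cmd[0] == "C":
            (x0, y0) = pts[-1]
            (x1, y1), (x2, y2), (x3, y3) = cmd[1], cmd[2], cmd[3]
            for i in range(1, n + 1):
                t = i / n
                mt = 1.0 - t
                pts.append((
                    mt**3 * x0 + 3 * mt**2 * t * x1 + 3 * mt * t**2 * x2 + t**3 * x3,
                    mt**3 * y0 + 3 * mt**2 * t * y1 + 3 * mt * t**2 * y2 + t**3 * y3,
                ))
        elif cmd[0] == "Z" and start is not None:
            pts.append(start)
    return pts


# --------------------------------------------------------------------------
# Layout -> Scene
# --------------------------------------------------------------------------


def layout_to_scene(layout: LayoutResult, config: PlotConfig) -> Scene:
    """Serialize a layout into painter's order: spans, marks, labels."""
    prims: list[Primitive] = []
    meta = layout.meta

    for span in layout.spans:
        if isinstance(span, ArcSpan):
            idx = meta["chrom_index"][span.chrom_id]
            prims.append(Primitive(
                "arc_band",
                (*meta["center"], meta["r_inner"], meta["r_outer"],
                 span.theta_start, span.theta_end),
                Style(fill=config.color(idx)),
            ))
        elif isinstance(span, LinearSpan):
            if span.thickness == 0.0:  # dot plot axis interval
                if span.vertical:
                    pts = ((span.y, span.x_start), (span.y, span.x_end))
                else:
                    pts = ((span.x_start, span.y), (span.x_end, span.y))
                prims.append(Primitive(
                    "segment", pts, Style(stroke="#333333", stroke_width=1.5)
                ))
            else:
                if span.vertical:
                    idx = meta.get("chrom_index", {}).get(span.chrom_id, span.track)
                    fill = config.color(idx)
                    rect = (
                        (span.y, span.x_start),
                        (span.y + span.thickness, span.x_start),
                        (span.y + span.thickness, span.x_end),
                        (span.y, span.x_end),
                    )
                else:
                    fill = BAR_FILL
                    rect = (
                        (span.x_start, span.y),
                        (span.x_end, span.y),
                        (span.x_end, span.y + span.thickness),
                        (span.x_start, span.y + span.thickness),
                    )
                prims.append(Primitive("polygon", rect, Style(fill=fill)))

    dot_r = max(1.5, 0.003 * min(layout.canvas))
    for mark in layout.marks:
        if isinstance(mark, RibbonGeometry):
            (c1a, c1b), (c2a, c2b) = mark.control_points
            prims.append(Primitive(
                "cubic_ribbon",
                (*mark.center, mark.radius, *mark.arc_a, *mark.arc_b,
                 c1a, c1b, c2a, c2b),
                Style(fill=mark.fill_color, opacity=mark.opacity),
            ))
        elif isinstance(mark, IntervalMark):
            prims.append(Primitive(
                "polygon",
                ((mark.x0, mark.y), (mark.x1, mark.y),
                 (mark.x1, mark.y + mark.height), (mark.x0, mark.y + mark.height)),
                Style(fill=mark.color),
            ))
        elif isinstance(mark, BandMark):
            prims.append(Primitive(
                "polygon", mark.corners,
                Style(fill=mark.color, opacity=mark.opacity),
            ))
        elif isinstance(mark, DotMark):
            prims.append(Primitive(
                "circle_marker", ((mark.x, mark.y), dot_r),
                Style(fill=mark.color),
            ))
        elif isinstance(mark, SegmentMark):
            prims.append(Primitive(
                "segment", ((mark.x0, mark.y0), (mark.x1, mark.y1)),
                Style(stroke=mark.color, stroke_width=mark.width),
            ))
        else:
            raise RenderError(f"unknown mark type {type(mark).__name__}")

    for lab in layout.labels:
        prims.append(Primitive(
            "text",
            (lab.x, lab.y, lab.text, lab.rotation, lab.anchor),
            Style(fill="#000000", font_size=lab.font_size),
        ))

    w, h = layout.canvas
    return Scene(w, h, config.background, tuple(prims))


# --------------------------------------------------------------------------
# Shared helpers
# --------------------------------------------------------------------------


def _fmt(v: float) -> str:
    """Deterministic short decimal for coordinates."""
    s = f"{v:.3f}".rstrip("0").rstrip(".")
    return "0" if s in ("-0", "") else s


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    return tuple(int(color[i:i + 2], 16) for i in (1, 3, 5))  # type: ignore


def _blend(color: str, alpha: float, bg: str) -> tuple[float, float, float]:
    """Alpha-composite a color over the background (0..1 channels)."""
    c = _hex_to_rgb(color)
    b = _hex_to_rgb(bg)
    return tuple((b[i] + alpha * (c[i] - b[i])) / 255.0 for i in range(3))  # type: ignore


def _xml_escape(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;").replace('"', "&quot;"))


def _ps_escape(s: str) -> str:
    return s.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")


# --------------------------------------------------------------------------
# SVG
# --------------------------------------------------------------------------


def _write_svg(scene: Scene) -> bytes:
    w, h = _fmt(scene.width), _fmt(scene.height)
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}pt" '
        f'height="{h}pt" viewBox="0 0 {w} {h}">',
        f'<rect class="background" width="{w}" height="{h}" '
        f'fill="{scene.background}"/>',
    ]
    for prim in scene.primitives:
        st = prim.style
        if prim.kind == "text":
            x, y, text, rot, anchor = prim.geometry
            attrs = (
                f'x="{_fmt(x)}" y="{_fmt(y)}" font-size="{_fmt(st.font_size)}" '
                f'font-family="{FONT_FAMILY}" fill="{st.fill or "#000000"}" '
                f'text-anchor="{anchor}"'
            )
            if rot:
                attrs += f' transform="rotate({_fmt(rot)} {_fmt(x)} {_fmt(y)})"'
            out.append(f"<text {attrs}>{_xml_escape(text)}</text>")
            continue
        if prim.kind == "circle_marker":
            (cx, cy), r = prim.geometry
            out.append(
                f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}" '
                f'fill="{st.fill}"'
                + (f' fill-opacity="{_fmt(st.opacity)}"' if st.opacity < 1 else "")
                + "/>"
            )
            continue
        d = []
        for cmd in primitive_path(prim):
            if cmd[0] == "M":
                d.append(f"M{_fmt(cmd[1][0])},{_fmt(cmd[1][1])}")
            elif cmd[0] == "L":
                d.append(f"L{_fmt(cmd[1][0])},{_fmt(cmd[1][1])}")
            elif cmd[0] == "C":
                d.append(
                    "C" + " ".join(
                        f"{_fmt(p[0])},{_fmt(p[1])}" for p in cmd[1:4]
                    )
                )
            else:
                d.append("Z")
        attrs = [f'd="{" ".join(d)}"']
        if st.fill:
            attrs.append(f'fill="{st.fill}"')
            if st.opacity < 1:
                attrs.append(f'fill-opacity="{_fmt(st.opacity)}"')
        else:
            attrs.append('fill="none"')
        if st.stroke:
            attrs.append(f'stroke="{st.stroke}" '
                         f'stroke-width="{_fmt(st.stroke_width)}"')
            if st.opacity < 1:
                attrs.append(f'stroke-opacity="{_fmt(st.opacity)}"')
        out.append(f'<path {" ".join(attrs)}/>')
    out.append("</svg>")
    return ("\n".join(out) + "\n").encode("utf-8")


# --------------------------------------------------------------------------
# EPS
# --------------------------------------------------------------------------


def _write_eps(scene: Scene) -> bytes:
    """EPS writer; opacity is pre-blended against the background color
    (PostScript has no alpha channel)."""
    W, H = scene.width, scene.height
    out = [
        "%!PS-Adobe-3.0 EPSF-3.0",
        f"%%BoundingBox: 0 0 {math.ceil(W)} {math.ceil(H)}",
        "%%Pages: 1",
        "%%DocumentFonts: Helvetica",
        "%%EndComments",
        f"/{FONT_FAMILY} findfont",
        "pop",
    ]

    def pt(p):  # canvas -> PS coords (y up)
        return f"{_fmt(p[0])} {_fmt(H - p[1])}"

    def setcolor(color: str, alpha: float):
        r, g, b = _blend(color, alpha, scene.background)
        out.append(f"{_fmt(r)} {_fmt(g)} {_fmt(b)} setrgbcolor")

    # background
    out.append("gsave")
    setcolor(scene.background, 1.0)
    out.append(f"newpath 0 0 moveto {_fmt(W)} 0 lineto "
               f"{_fmt(W)} {_fmt(H)} lineto 0 {_fmt(H)} lineto closepath fill")
    out.append("grestore")

    for prim in scene.primitives:
        st = prim.style
        if prim.kind == "text":
            x, y, text, rot, anchor = prim.geometry
            out.append("gsave")
            setcolor(st.fill or "#000000", st.opacity)
            out.append(f"/{FONT_FAMILY} findfont {_fmt(st.font_size)} "
                       "scalefont setfont")
            out.append(f"{pt((x, y))} translate")
            if rot:
                out.append(f"{_fmt(-rot)} rotate")
            out.append("0 0 moveto")
            esc = _ps_escape(text)
            if anchor == "middle":
                out.append(f"({esc}) dup stringwidth pop 2 div neg 0 rmoveto show")
            elif anchor == "end":
                out.append(f"({esc}) dup stringwidth pop neg 0 rmoveto show")
            else:
                out.append(f"({esc}) show")
            out.append("grestore")
            continue
        if prim.kind == "circle_marker":
            (cx, cy), r = prim.geometry
            setcolor(st.fill or "#000000", st.opacity)
            out.append(f"newpath {pt((cx, cy))} {_fmt(r)} 0 360 arc closepath fill")
            continue
        parts = ["newpath"]
        for cmd in primitive_path(prim):
            if cmd[0] == "M":
                parts.append(f"{pt(cmd[1])} moveto")
            elif cmd[0] == "L":
                parts.append(f"{pt(cmd[1])} lineto")
            elif cmd[0] == "C":
                parts.append(
                    f"{pt(cmd[1])} {pt(cmd[2])} {pt(cmd[3])} curveto"
                )
            else:
                parts.append("closepath")
        if st.fill:
            setcolor(st.fill, st.opacity)
            parts.append("fill")
        else:
            setcolor(st.stroke or "#000000", st.opacity)
            parts.append(f"{_fmt(st.stroke_width)} setlinewidth stroke")
        out.append(" ".join(parts))

    out.append("showpage")
    out.append("%%EOF")
    return ("\n".join(out) + "\n").encode("ascii", "replace")


# --------------------------------------------------------------------------
# PDF
# --------------------------------------------------------------------------


def _pdf_text_offset(text: str, font_size: float, anchor: str) -> float:
    width = APPROX_CHAR_WIDTH * font_size * len(text)
    if anchor == "middle":
        return -width / 2.0
    if anchor == "end":
        return -width
    return 0.0


def _write_pdf(scene: Scene) -> bytes:
    """Minimal single-page PDF with an uncompressed content stream.

    Opacity goes through ExtGState alpha entries; text uses the built-in
    Helvetica with approximate metrics for anchoring.
    """
    W, H = scene.width, scene.height

    alphas = sorted({
        p.style.opacity for p in scene.primitives if p.style.opacity < 1.0
    })
    alpha_names = {a: f"GS{i}" for i, a in enumerate(alphas)}

    c = []  # content stream lines

    def rgb(color: str, alpha: float, stroke: bool) -> None:
        if alpha < 1.0:
            c.append(f"/{alpha_names[alpha]} gs")
        r, g, b = (v / 255.0 for v in _hex_to_rgb(color))
        op = "RG" if stroke else "rg"
        c.append(f"{_fmt(r)} {_fmt(g)} {_fmt(b)} {op}")

    def pt(p) -> str:
        return f"{_fmt(p[0])} {_fmt(H - p[1])}"

    # background
    c.append("q")
    rgb(scene.background, 1.0, stroke=False)
    c.append(f"0 0 {_fmt(W)} {_fmt(H)} re")
    c.append("f")
    c.append("Q")

    for prim in scene.primitives:
        st = prim.style
        c.append("q")
        if prim.kind == "text":
            x, y, text, rot, anchor = prim.geometry
            rgb(st.fill or "#000000", st.opacity, stroke=False)
            dx = _pdf_text_offset(text, st.font_size, anchor)
            a = math.radians(-rot)
            cos_a, sin_a = math.cos(a), math.sin(a)
            tx = x + dx * math.cos(math.radians(rot))
            ty = y + dx * math.sin(math.radians(rot))
            c.append("BT")
            c.append(f"/F1 {_fmt(st.font_size)} Tf")
            c.append(
                f"{_fmt(cos_a)} {_fmt(sin_a)} {_fmt(-sin_a)} {_fmt(cos_a)} "
                f"{pt((tx, ty))} Tm"
            )
            esc = text.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")
            c.append(f"({esc}) Tj")
            c.append("ET")
            c.append("Q")
            continue
        if prim.kind == "circle_marker":
            (cx, cy), r = prim.geometry
            rgb(st.fill or "#000000", st.opacity, stroke=False)
            # draw via the shared arc flattening (full circle)
            k = (4.0 / 3.0) * math.tan(math.pi / 8.0)
            yy = H - cy
            c.append(f"{_fmt(cx + r)} {_fmt(yy)} m")
            for q in range(4):
                a0 = q * math.pi / 2.0
                a1 = a0 + math.pi / 2.0
                p0 = (cx + r * math.cos(a0), yy + r * math.sin(a0))
                p1 = (cx + r * math.cos(a1), yy + r * math.sin(a1))
                t0 = (-r * math.sin(a0), r * math.cos(a0))
                t1 = (-r * math.sin(a1), r * math.cos(a1))
                c.append(
                    f"{_fmt(p0[0] + k * t0[0])} {_fmt(p0[1] + k * t0[1])} "
                    f"{_fmt(p1[0] - k * t1[0])} {_fmt(p1[1] - k * t1[1])} "
                    f"{_fmt(p1[0])} {_fmt(p1[1])} c"
                )
            c.append("h")
            c.append("f")
            c.append("Q")
            continue
        for cmd in primitive_path(prim):
            if cmd[0] == "M":
                c.append(f"{pt(cmd[1])} m")
            elif cmd[0] == "L":
                c.append(f"{pt(cmd[1])} l")
            elif cmd[0] == "C":
                c.append(f"{pt(cmd[1])} {pt(cmd[2])} {pt(cmd[3])} c")
            else:
                c.append("h")
        if st.fill:
            rgb(st.fill, st.opacity, stroke=False)
            c.append("f")
        else:
            rgb(st.stroke or "#000000", st.opacity, stroke=True)
            c.append(f"{_fmt(st.stroke_width)} w")
            c.append("S")
        c.append("Q")

    content = ("\n".join(c) + "\n").encode("ascii", "replace")

    ext_gstates = "".join(
        f"/{name} {6 + i} 0 R " for i, name in enumerate(alpha_names.values())
    )
    objects: list[bytes] = [
        b"<< /Type /Catalog /Pages 2 0 R >>",
        f"<< /Type /Pages /Kids [3 0 R] /Count 1 >>".encode(),
        (
            f"<< /Type /Page /Parent 2 0 R /MediaBox [0 0 {_fmt(W)} {_fmt(H)}] "
            f"/Contents 4 0 R /Resources << /Font << /F1 5 0 R >> "
            f"/ExtGState << {ext_gstates}>> >> >>"
        ).encode(),
        (f"<< /Length {len(content)} >>\nstream\n".encode() + content
         + b"endstream"),
        (f"<< /Type /Font /Subtype /Type1 /BaseFont /{FONT_FAMILY} >>").encode(),
    ]
    for a in alphas:
        objects.append(f"<< /Type /ExtGState /ca {_fmt(a)} /CA {_fmt(a)} >>".encode())

    buf = bytearray(b"%PDF-1.4\n%\xe2\xe3\xcf\xd3\n")
    offsets = [0]
    for i, obj in enumerate(objects, start=1):
        offsets.append(len(buf))
        buf += f"{i} 0 obj\n".encode() + obj + b"\nendobj\n"
    xref_at = len(buf)
    n = len(objects) + 1
    buf += f"xref\n0 {n}\n".encode()
    buf += b"0000000000 65535 f \n"
    for off in offsets[1:]:
        buf += f"{off:010d} 00000 n \n".encode()
    buf += (
        f"trailer\n<< /Size {n} /Root 1 0 R >>\nstartxref\n{xref_at}\n%%EOF\n"
    ).encode()
    return bytes(buf)


# --------------------------------------------------------------------------
# Raster (Pillow)
# --------------------------------------------------------------------------


def _raster_image(scene: Scene, dpi: int) -> Image.Image:
    s = dpi / 72.0
    tw = round(scene.width * dpi / 72.0)
    th = round(scene.height * dpi / 72.0)
    base = Image.new("RGBA", (tw, th), (*_hex_to_rgb(scene.background), 255))
    draw = ImageDraw.Draw(base)
    font_cache: dict[int, ImageFont.ImageFont] = {}

    def get_font(size_px: int):
        if size_px not in font_cache:
            try:
                font_cache[size_px] = ImageFont.load_default(size=size_px)
            except TypeError:  # very old Pillow
                font_cache[size_px] = ImageFont.load_default()
        return font_cache[size_px]

    def sp(p) -> tuple[float, float]:
        return (p[0] * s, p[1] * s)

    for prim in scene.primitives:
        st = prim.style
        if prim.kind == "text":
            x, y, text, rot, anchor = prim.geometry
            size_px = max(6, round(st.font_size * s))
            font = get_font(size_px)
            color = (*_hex_to_rgb(st.fill or "#000000"), round(255 * st.opacity))
            bbox = font.getbbox(text)
            tw_px = bbox[2] - bbox[0]
            th_px = bbox[3] - bbox[1]
            pad = 2
            tile = Image.new("RGBA", (tw_px + 2 * pad, th_px + 2 * pad),
                             (0, 0, 0, 0))
            ImageDraw.Draw(tile).text((pad - bbox[0], pad - bbox[1]),
                                      text, font=font, fill=color)
            if rot:
                tile = tile.rotate(-rot, expand=True,
                                   resample=Image.Resampling.BICUBIC)
            ax, ay = sp((x, y))
            # shift so the anchor lands on the rotation-invariant center
            if anchor == "middle":
                off = 0.0
            elif anchor == "end":
                off = -tw_px / 2.0
            else:
                off = tw_px / 2.0
            rad = math.radians(rot)
            ax += off * math.cos(rad)
            ay += off * math.sin(rad)
            base.alpha_composite(
                tile,
                (round(ax - tile.width / 2.0), round(ay - tile.height / 2.0)),
            )
            continue
        if prim.kind == "circle_marker":
            (cx, cy), r = prim.geometry
            (cx, cy), r = sp((cx, cy)), r * s
            color = (*_hex_to_rgb(st.fill or "#000000"), round(255 * st.opacity))
            draw.ellipse((cx - r, cy - r, cx + r, cy + r), fill=color)
            continue

        pts = [sp(p) for p in _flatten(primitive_path(prim))]
        if prim.kind == "segment":
            color = (*_hex_to_rgb(st.stroke or "#000000"),
                     round(255 * st.opacity))
            draw.line(pts, fill=color, width=max(1, round(st.stroke_width * s)))
            continue
        alpha = round(255 * st.opacity)
        color = (*_hex_to_rgb(st.fill or st.stroke or "#000000"), alpha)
        if alpha == 255:
            draw.polygon(pts, fill=color)
        else:
            # translucent fills must composite, not overwrite: draw on a
            # bounding-box-sized overlay and alpha-composite it in place
            xs = [p[0] for p in pts]
            ys = [p[1] for p in pts]
            x0 = max(0, math.floor(min(xs)) - 1)
            y0 = max(0, math.floor(min(ys)) - 1)
            x1 = min(tw, math.ceil(max(xs)) + 1)
            y1 = min(th, math.ceil(max(ys)) + 1)
            if x1 <= x0 or y1 <= y0:
                continue
            tile = Image.new("RGBA", (x1 - x0, y1 - y0), (0, 0, 0, 0))
            ImageDraw.Draw(tile).polygon(
                [(p[0] - x0, p[1] - y0) for p in pts], fill=color
            )
            base.alpha_composite(tile, (x0, y0))

    return base


# --------------------------------------------------------------------------
# Dispatch
# --------------------------------------------------------------------------


def render(
    scene: Scene,
    out_format: str,
    path: str | PathLike,
    raster_dpi: int = 300,
) -> Path:
    """Write a scene to one file; returns the path written."""
    fmt = out_format.lower()
    if fmt == "jpg":
        fmt = "jpeg"
    if fmt not in OUT_FORMATS:
        raise RenderError(
            f"unknown output format {out_format!r}; "
            f"supported: {', '.join(OUT_FORMATS)}"
        )
    path = Path(path)
    if fmt == "svg":
        data = _write_svg(scene)
        path.write_bytes(data)
    elif fmt == "eps":
        path.write_bytes(_write_eps(scene))
    elif fmt == "pdf":
        path.write_bytes(_write_pdf(scene))
    else:
        img = _raster_image(scene, raster_dpi)
        if fmt == "png":
            img.save(path, format="PNG")
        elif fmt == "jpeg":
            img.convert("RGB").save(path, format="JPEG", quality=JPEG_QUALITY)
        else:
            img.convert("RGB").save(path, format="BMP")
    return path


def render_all_formats(
    scene: Scene, basename: str | PathLike, raster_dpi: int = 300
) -> dict[str, Path]:
    """Write one scene to all six formats: <basename>.<format>."""
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for fmt in OUT_FORMATS:
        try:
            written[fmt] = render(scene, fmt, base.with_name(f"{base.name}.{fmt}"),
                                  raster_dpi)
        except Exception as exc:
            raise RenderError(f"rendering {fmt} failed: {exc}") from exc
    return written
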