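"""Figure assembly and output: deterministic SVG, rasterized PNG.

The figure is first assembled as a flat, ordered list of primitives
(lines, polygons, text) with explicit canvas coordinates — list order
is z-order.  The draw order is: decoration tracks, homology ribbons,
sequence lines, feature glyphs, labels, then legend and scale, so
annotations stay legible on top of large homology blocks.  The SVG
serializer produces byte-identical output for identical documents (all
colors normalized to hex, floats formatted with a fixed rule); PNG is a
rasterization of the same primitive list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

from matplotlib.colors import to_hex, to_rgb

from ._version import __version__
from .decorations import DecorationSpec, Profile, scale_bar_model
from .errors import GenodrawError, LayoutError
from .featurestyle import FeatureSpec, ResolvedStyle, resolve_style
from .homology import HomologyHit
from .layout import LayoutModel
from .seqio import Feature, SequenceRecord

__all__ = [
    "Line",
    "Polygon",
    "TextLabel",
    "FigureDocument",
    "RibbonStyle",
    "normalize_color",
    "identity_color",
    "feature_glyph",
    "ribbon",
    "render_figure",
    "write_svg",
    "write_png",
]

ARROW_HEAD_MAX_PX = 12.0
MIN_GLYPH_WIDTH_PX = 1.0


# ---------------------------------------------------------------------------
# primitives


@dataclass(frozen=True)
class Line:
    x1: float
    y1: float
    x2: float
    y2: float
    color: str = "#000000"
    width: float = 1.0


@dataclass(frozen=True)
class Polygon:
    points: tuple[tuple[float, float], ...]
    fill: str = "#c8c8c8"
    outline: str | None = "#000000"
    outline_width: float = 1.0
    opacity: float = 1.0
    hatching: str = "none"


@dataclass(frozen=True)
class TextLabel:
    x: float
    y: float
    text: str
    size: float = 10.0
    color: str = "#000000"
    anchor: str = "middle"  # start | middle | end


Primitive = Line | Polygon | TextLabel


@dataclass
class FigureDocument:
    """Ordered draw list plus canvas size; order is z-order."""

    width: float
    height: float
    primitives: list[Primitive] = field(default_factory=list)
    generator: str = ""

    def __post_init__(self) -> None:
        if not self.generator:
            self.generator = f"genodraw {__version__}"


def normalize_color(color: str) -> str:
    """Any hex or named color -> lowercase ``#rrggbb`` hex."""
    try:
        return to_hex(color)
    except ValueError as exc:
        raise GenodrawError(f"unrecognized color {color!r}") from exc


# ---------------------------------------------------------------------------
# homology ribbons


@dataclass
class RibbonStyle:
    """Identity color ramp and opacity for homology ribbons."""

    color_min: str = "#d8d8f0"
    color_max: str = "#3030a0"
    opacity: float = 0.65
    min_identity: float = 0.0
    inverted_color: str | None = None  # optional distinct fill for inverted hits


def identity_color(
    percent_identity: float, style: RibbonStyle
) -> str:
    """Linear per-channel ramp from color_min (at the identity threshold)
    to color_max (at 100% identity)."""
    lo = max(0.0, min(100.0, style.min_identity))
    span = 100.0 - lo
    t = 1.0 if span <= 0 else (percent_identity - lo) / span
    t = max(0.0, min(1.0, t))
    c0 = to_rgb(normalize_color(style.color_min))
    c1 = to_rgb(normalize_color(style.color_max))
    mixed = tuple(a + (b - a) * t for a, b in zip(c0, c1))
    return to_hex(mixed)


def ribbon(
    hit: HomologyHit, layout: LayoutModel, style: RibbonStyle
) -> Polygon | None:
    """Quadrilateral joining a hit's intervals on its two sequences.

    The top edge spans the interval on the upper (smaller y) sequence,
    the bottom edge the interval on the lower one.  Direct hits give a
    trapezoid; inverted hits cross the side edges (left of the upper
    interval joins the right of the lower one), which reads as an
    inversion without any legend.  Hits touching a sequence missing
    from the layout (hidden or unknown) return ``None``.
    """
    for rid in (hit.query_id, hit.subject_id):
        if rid not in layout.y_centers:
            return None
    half = layout.lane_height / 2.0
    q_y = layout.y_centers[hit.query_id]
    s_y = layout.y_centers[hit.subject_id]
    qx1 = layout.x_px(hit.query_id, hit.q_start)
    qx2 = layout.x_px(hit.query_id, hit.q_end)
    sx1 = layout.x_px(hit.subject_id, hit.s_start)
    sx2 = layout.x_px(hit.subject_id, hit.s_end)
    if q_y <= s_y:
        top = (qx1, q_y + half), (qx2, q_y + half)
        bot_left, bot_right = (sx1, s_y - half), (sx2, s_y - half)
    else:
        top = (sx1, s_y + half), (sx2, s_y + half)
        bot_left, bot_right = (qx1, q_y - half), (qx2, q_y - half)
    if hit.inverted:
        vertices = (top[0], top[1], bot_left, bot_right)  # crossed sides
    else:
        vertices = (top[0], top[1], bot_right, bot_left)
    if style.inverted_color is not None and hit.inverted:
        fill = normalize_color(style.inverted_color)
    else:
        fill = identity_color(hit.percent_identity, style)
    return Polygon(
        points=vertices,
        fill=fill,
        outline=None,
        outline_width=0.0,
        opacity=style.opacity,
        hatching="none",
    )


# ---------------------------------------------------------------------------
# feature glyphs


def _segment_px(
    record: SequenceRecord, layout: LayoutModel, start: int, end: int
) -> tuple[float, float]:
    """Pixel x-extent of a segment, honouring reverse-complement display."""
    if record.display_options.reverse_complement:
        start, end = record.length_bp - end, record.length_bp - start
    x1 = layout.x_px(record.record_id, start)
    x2 = layout.x_px(record.record_id, end)
    if x2 - x1 < MIN_GLYPH_WIDTH_PX:  # keep tiny features visible
        pad = (MIN_GLYPH_WIDTH_PX - (x2 - x1)) / 2.0
        x1, x2 = x1 - pad, x2 + pad
    return x1, x2


def _shape_points(
    shape: str, x1: float, x2: float, yc: float, height: float, strand: int
) -> tuple[tuple[float, float], ...]:
    yt, yb = yc - height / 2.0, yc + height / 2.0
    width = x2 - x1
    head = min(ARROW_HEAD_MAX_PX, width)
    if shape == "box" or strand == 0:
        return ((x1, yt), (x2, yt), (x2, yb), (x1, yb))
    if shape == "pointer":  # head-only triangle across the whole segment
        if strand >= 0:
            return ((x1, yt), (x2, yc), (x1, yb))
        return ((x2, yt), (x1, yc), (x2, yb))
    # arrow: rectangle body + triangular head pointing with the strand
    if strand >= 0:
        xh = x2 - head
        return ((x1, yt), (xh, yt), (x2, yc), (xh, yb), (x1, yb))
    xh = x1 + head
    return ((x2, yt), (xh, yt), (x1, yc), (xh, yb), (x2, yb))


def feature_glyph(
    feature: Feature,
    style: ResolvedStyle,
    layout: LayoutModel,
    record: SequenceRecord,
) -> list[Primitive]:
    """Primitives for one feature: per-segment glyphs plus connectors.

    Multi-segment (``join``) features are drawn as one glyph per
    segment linked by a thin connector line; the strand arrow-head goes
    on the last segment in transcription order so a joined gene reads
    as one unit.
    """
    if style.hidden:
        return []
    yc = layout.y_centers[record.record_id]
    strand = feature.strand
    if record.display_options.reverse_complement:
        strand = -strand
    prims: list[Primitive] = []
    segs = feature.segments
    head_seg = len(segs) - 1 if strand >= 0 else 0
    for i, (start, end) in enumerate(segs):
        x1, x2 = _segment_px(record, layout, start, end)
        shape = style.shape
        if len(segs) > 1 and i != head_seg and shape in ("arrow", "pointer"):
            shape = "box"  # only the terminal segment carries the head
        prims.append(
            Polygon(
                points=_shape_points(shape, x1, x2, yc, style.height, strand),
                fill=normalize_color(style.fill_color),
                outline=normalize_color(style.outline_color),
                outline_width=style.outline_width,
                hatching=style.hatching,
            )
        )
    for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
        xa = _segment_px(record, layout, s1, e1)
        xb = _segment_px(record, layout, s2, e2)
        lo, hi = min(xa[1], xb[0]), max(xa[1], xb[0])
        prims.append(Line(lo, yc, hi, yc, color="#666666", width=0.8))
    if style.label_visible:
        values = feature.qualifier_values(style.label_text_source)
        if values:
            x1, _ = _segment_px(record, layout, feature.start, feature.end)
            _, x2 = _segment_px(record, layout, feature.start, feature.end)
            prims.append(
                TextLabel(
                    x=(x1 + x2) / 2.0,
                    y=yc - style.height / 2.0 - 3.0,
                    text=values[0],
                    size=8.0,
                    anchor="middle",
                )
            )
    return prims


# ---------------------------------------------------------------------------
# decoration tracks


def _track_primitives(
    profile: Profile,
    spec: DecorationSpec,
    layout: LayoutModel,
    record: SequenceRecord,
    y_top: float,
) -> list[Primitive]:
    """Filled area between the profile curve and its baseline.

    GC content is drawn around the profile mean, GC-skew around zero,
    with distinct colors above and below the baseline.
    """
    if not profile.values:
        return []
    h = spec.track_height_px
    if profile.kind == "gc_content":
        baseline_v = sum(profile.values) / len(profile.values)
        # scale to the observed range so local variation stays visible
        lo, hi = min(profile.values), max(profile.values)
        pad = max(0.01, (hi - lo) * 0.1)
        vmin, vmax = max(0.0, lo - pad), min(1.0, hi + pad)
    else:
        baseline_v = 0.0
        vmin, vmax = -1.0, 1.0

    def y_of(v: float) -> float:
        frac = (v - vmin) / (vmax - vmin)
        return y_top + h * (1.0 - frac)

    base_y = y_of(baseline_v)
    prims: list[Primitive] = []
    xs = [layout.x_px(record.record_id, p) for p in profile.positions]
    for (x1, v1), (x2, v2) in zip(
        zip(xs, profile.values), zip(xs[1:], profile.values[1:])
    ):
        mid = (v1 + v2) / 2.0
        color = spec.color_above if mid >= baseline_v else spec.color_below
        prims.append(
            Polygon(
                points=((x1, base_y), (x1, y_of(v1)), (x2, y_of(v2)), (x2, base_y)),
                fill=normalize_color(color),
                outline=None,
                outline_width=0.0,
                opacity=0.9,
            )
        )
    x_lo, x_hi = xs[0], xs[-1]
    prims.append(Line(x_lo, base_y, x_hi, base_y, color="#888888", width=0.6))
    return prims


def _scale_bar_primitives(
    layout: LayoutModel,
    record: SequenceRecord,
    y_top: float,
    height: float,
    tick_target: int = 5,
) -> list[Primitive]:
    bar = scale_bar_model(record.length_bp, tick_target)
    y_axis = y_top + 4.0
    prims: list[Primitive] = [
        Line(
            layout.x_px(record.record_id, 0),
            y_axis,
            layout.x_px(record.record_id, record.length_bp),
            y_axis,
            width=1.0,
        )
    ]
    for pos, label in zip(bar.ticks_bp, bar.labels):
        x = layout.x_px(record.record_id, pos)
        prims.append(Line(x, y_axis, x, y_axis + 4.0, width=1.0))
        prims.append(TextLabel(x, y_axis + 13.0, label, size=8.0))
    return prims


# ---------------------------------------------------------------------------
# full figure


@dataclass
class LegendConfig:
    show: bool = True
    swatch_px: float = 12.0
    font_size: float = 9.0


@dataclass
class RenderInput:
    """Everything the renderer needs, already resolved and laid out."""

    records: list[SequenceRecord]  # display order; inactive entries skipped
    cascade: list[FeatureSpec]
    defaults: ResolvedStyle
    draw_unmatched: bool
    hits_by_pair: dict[tuple[str, str], list[HomologyHit]]
    layout: LayoutModel
    decorations: list[DecorationSpec] = field(default_factory=list)
    profiles: dict[tuple[str, int], Profile] = field(default_factory=dict)
    ribbon_style: RibbonStyle = field(default_factory=RibbonStyle)
    legend: LegendConfig = field(default_factory=LegendConfig)


def render_figure(inp: RenderInput) -> FigureDocument:
    """Assemble the full draw list in z-order."""
    active = [r for r in inp.records if r.active]
    if not active:
        raise LayoutError("no active sequences: nothing to render")
    layout = inp.layout
    # horizontal offsets (best-blast / manual) may push content past the
    # configured width; the document grows to fit rather than clipping
    content_right = max(
        layout.x_px(r.record_id, r.length_bp) for r in active
    )
    width = max(layout.canvas_width, content_right + layout.margin)
    doc = FigureDocument(width=width, height=layout.canvas_height)
    by_id = {r.record_id: r for r in active}

    # 1. decoration tracks
    for box in layout.track_boxes:
        rec = by_id[box.record_id]
        spec = inp.decorations[box.decoration_index]
        if spec.kind == "scale_bar":
            doc.primitives.extend(
                _scale_bar_primitives(layout, rec, box.y_top, box.height)
            )
        else:
            profile = inp.profiles.get((box.record_id, box.decoration_index))
            if profile is not None:
                doc.primitives.extend(
                    _track_primitives(profile, spec, layout, rec, box.y_top)
                )

    # 2. homology ribbons (beneath sequence lines and glyphs)
    active_ids = set(by_id)
    for pair in sorted(inp.hits_by_pair):
        if not (pair[0] in active_ids and pair[1] in active_ids):
            continue
        for hit in inp.hits_by_pair[pair]:
            poly = ribbon(hit, layout, inp.ribbon_style)
            if poly is not None:
                doc.primitives.append(poly)

    # 3. sequence lines
    for rec in active:
        y = layout.y_centers[rec.record_id]
        doc.primitives.append(
            Line(
                layout.x_px(rec.record_id, 0),
                y,
                layout.x_px(rec.record_id, rec.length_bp),
                y,
                color=normalize_color(rec.display_options.line_color),
                width=rec.display_options.line_width,
            )
        )

    # 4. feature glyphs
    for rec in active:
        for feat in rec.features:
            style = resolve_style(feat, inp.cascade, inp.defaults)
            if not style.matched_spec_indices and not inp.draw_unmatched:
                continue
            doc.primitives.extend(feature_glyph(feat, style, layout, rec))

    # 5. sequence name labels
    for rec in active:
        label = rec.display_options.label or rec.display_name
        doc.primitives.append(
            TextLabel(
                x=layout.x_px(rec.record_id, 0),
                y=layout.y_centers[rec.record_id] - layout.lane_height / 2.0 - 8.0,
                text=label,
                size=10.0,
                anchor="start",
            )
        )

    # 6. legend: one swatch per labelled cascade spec
    if inp.legend.show:
        entries = [s for s in inp.cascade if s.label]
        x = layout.margin
        y = layout.canvas_height - layout.margin / 2.0
        sw = inp.legend.swatch_px
        for spec in entries:
            fill = spec.style.fill_color or inp.defaults.fill_color
            hatching = spec.style.hatching or "none"
            doc.primitives.append(
                Polygon(
                    points=(
                        (x, y - sw),
                        (x + sw, y - sw),
                        (x + sw, y),
                        (x, y),
                    ),
                    fill=normalize_color(fill),
                    outline="#000000",
                    outline_width=0.8,
                    hatching=hatching,
                )
            )
            doc.primitives.append(
                TextLabel(
                    x=x + sw + 4.0,
                    y=y - 2.0,
                    text=spec.label,
                    size=inp.legend.font_size,
                    anchor="start",
                )
            )
            x += sw + 10.0 + 6.2 * len(spec.label)
    return doc


# ---------------------------------------------------------------------------
# SVG output


def _f(v: float) -> str:
    """Fixed float formatting: 2 decimals, trailing zeros trimmed."""
    s = f"{v:.2f}".rstrip("0").rstrip(".")
    return s if s not in ("", "-0") else "0"


def _hatch_pattern_id(hatching: str, fill: str) -> str:
    return f"hatch-{hatching}-{fill.lstrip('#')}"


_HATCH_LINES = {
    "diagonal": ["M0,6 L6,0"],
    "horizontal": ["M0,3 L6,3"],
    "vertical": ["M3,0 L3,6"],
    "cross": ["M0,3 L6,3", "M3,0 L3,6"],
}


def _pattern_def(hatching: str, fill: str) -> str:
    pid = _hatch_pattern_id(hatching, fill)
    paths = "".join(
        f'<path d="{d}" stroke="#000000" stroke-width="0.8"/>'
        for d in _HATCH_LINES[hatching]
    )
    return (
        f'<pattern id="{pid}" width="6" height="6" patternUnits="userSpaceOnUse">'
        f'<rect width="6" height="6" fill="{fill}"/>{paths}</pattern>'
    )


def _svg_element(prim: Primitive) -> str:
    if isinstance(prim, Line):
        return (
            f'<line x1="{_f(prim.x1)}" y1="{_f(prim.y1)}" x2="{_f(prim.x2)}" '
            f'y2="{_f(prim.y2)}" stroke="{prim.color}" '
            f'stroke-width="{_f(prim.width)}"/>'
        )
    if isinstance(prim, Polygon):
        pts = " ".join(f"{_f(x)},{_f(y)}" for x, y in prim.points)
        if prim.hatching != "none":
            fill = f"url(#{_hatch_pattern_id(prim.hatching, prim.fill)})"
        else:
            fill = prim.fill
        stroke = (
            f'stroke="{prim.outline}" stroke-width="{_f(prim.outline_width)}" '
            if prim.outline
            else 'stroke="none" '
        )
        opacity = f'opacity="{_f(prim.opacity)}" ' if prim.opacity < 1.0 else ""
        return f'<polygon points="{pts}" fill="{fill}" {stroke}{opacity}/>'
    if isinstance(prim, TextLabel):
        return (
            f'<text x="{_f(prim.x)}" y="{_f(prim.y)}" '
            f'font-family="sans-serif" font-size="{_f(prim.size)}" '
            f'fill="{prim.color}" text-anchor="{prim.anchor}">'
            f"{escape(prim.text)}</text>"
        )
    raise TypeError(f"unknown primitive {type(prim).__name__}")


def svg_text(doc: FigureDocument) -> str:
    """Serialize the document; byte-deterministic for a fixed version."""
    patterns: dict[str, str] = {}
    for prim in doc.primitives:
        if isinstance(prim, Polygon) and prim.hatching != "none":
            pid = _hatch_pattern_id(prim.hatching, prim.fill)
            patterns.setdefault(pid, _pattern_def(prim.hatching, prim.fill))
    defs = ""
    if patterns:
        defs = "<defs>" + "".join(patterns[k] for k in sorted(patterns)) + "</defs>\n"
    body = "\n".join(_svg_element(p) for p in doc.primitives)
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(doc.width)}" height="{_f(doc.height)}" '
        f'viewBox="0 0 {_f(doc.width)} {_f(doc.height)}">\n'
        f"<!-- generated by {escape(doc.generator)} -->\n"
        f'<rect width="{_f(doc.width)}" height="{_f(doc.height)}" fill="#ffffff"/>\n'
        f"{defs}{body}\n</svg>\n"
    )


def write_svg(doc: FigureDocument, path: str | Path) -> None:
    Path(path).write_text(svg_text(doc))


# ---------------------------------------------------------------------------
# PNG output (rasterization of the same primitive list)

_MPL_HATCH = {"diagonal": "//", "horizontal": "-", "vertical": "|", "cross": "+"}


def write_png(doc: FigureDocument, path: str | Path, dpi: int = 300) -> None:
    """Rasterize the document with the Agg backend at the requested dpi."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon

    # canvas px are CSS px (96/inch); dpi scales the raster density
    fig = plt.figure(figsize=(doc.width / 96.0, doc.height / 96.0))
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, doc.width)
    ax.set_ylim(doc.height, 0)  # y grows downwards, like SVG
    ax.axis("off")
    for prim in doc.primitives:
        if isinstance(prim, Line):
            ax.plot(
                [prim.x1, prim.x2],
                [prim.y1, prim.y2],
                color=prim.color,
                linewidth=prim.width,
                solid_capstyle="butt",
            )
        elif isinstance(prim, Polygon):
            patch = MplPolygon(
                list(prim.points),
                closed=True,
                facecolor=prim.fill,
                edgecolor=prim.outline or "none",
                linewidth=prim.outline_width,
                alpha=prim.opacity,
                hatch=_MPL_HATCH.get(prim.hatching),
            )
            ax.add_patch(patch)
        elif isinstance(prim, TextLabel):
            ha = {"start": "left", "middle": "center", "end": "right"}[prim.anchor]
            ax.text(
                prim.x,
                prim.y,
                prim.text,
                fontsize=prim.size * 72.0 / 96.0,
                color=prim.color,
                ha=ha,
                va="baseline",
                family="sans-serif",
            )
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
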