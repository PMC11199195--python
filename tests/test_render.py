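"""Glyph geometry, ribbon geometry, the identity ramp, and SVG output."""

import xml.etree.ElementTree as ET

import pytest

from genodraw.featurestyle import PartialStyle, default_style, FeatureSpec
from genodraw.homology import HomologyHit
from genodraw.layout import build_layout
from genodraw.render import (
    Line,
    Polygon,
    RibbonStyle,
    TextLabel,
    feature_glyph,
    identity_color,
    normalize_color,
    render_figure,
    ribbon,
    svg_text,
    write_png,
    write_svg,
)
from genodraw.seqio import Feature, SequenceRecord


def _rec(rid, length, features=(), residues=None):
    return SequenceRecord(
        record_id=rid,
        display_name=rid,
        length_bp=length,
        residues=residues,
        features=list(features),
    )


def _layout(records, **kw):
    kw.setdefault("canvas_width", 1080.0)  # margin 40 -> drawable 1000
    return build_layout(records, {}, **kw)


def _hit(qid, sid, qs, qe, ss, se, identity=95.0, inverted=False):
    return HomologyHit(
        query_id=qid,
        subject_id=sid,
        q_start=qs,
        q_end=qe,
        s_start=ss,
        s_end=se,
        percent_identity=identity,
        align_length=qe - qs,
        evalue=0.0,
        bitscore=100.0,
        inverted=inverted,
    )


class TestFeatureGlyph:
    def test_forward_arrow_spans_scaled_width_with_head_on_the_right(self):
        feat = Feature(ftype="CDS", segments=[(2000, 3000)], strand=1)
        rec = _rec("A", 10000, [feat])
        layout = _layout([rec])  # 0.1 px/bp
        (poly,) = feature_glyph(feat, default_style(), layout, rec)
        xs = [x for x, _ in poly.points]
        assert max(xs) - min(xs) == pytest.approx(100.0)
        tip_x = max(xs)
        yc = layout.y_centers["A"]
        assert (tip_x, yc) in poly.points  # head apex at the right edge

    def test_reverse_strand_arrow_mirrors_head_to_the_left(self):
        feat = Feature(ftype="CDS", segments=[(2000, 3000)], strand=-1)
        rec = _rec("A", 10000, [feat])
        layout = _layout([rec])
        (poly,) = feature_glyph(feat, default_style(), layout, rec)
        xs = [x for x, _ in poly.points]
        assert (min(xs), layout.y_centers["A"]) in poly.points

    def test_two_segment_join_gives_two_bodies_and_one_connector(self):
        feat = Feature(
            ftype="CDS", segments=[(1000, 2000), (3000, 4000)], strand=1
        )
        rec = _rec("A", 10000, [feat])
        layout = _layout([rec])
        prims = feature_glyph(feat, default_style(), layout, rec)
        polys = [p for p in prims if isinstance(p, Polygon)]
        lines = [p for p in prims if isinstance(p, Line)]
        assert len(polys) == 2 and len(lines) == 1

    def test_sub_pixel_feature_widened_to_one_pixel(self):
        feat = Feature(ftype="CDS", segments=[(5000, 5004)], strand=1)
        rec = _rec("A", 100000, [feat])
        layout = _layout([rec])  # 0.01 px/bp: 4 bp -> 0.04 px
        (poly,) = feature_glyph(feat, default_style(), layout, rec)
        xs = [x for x, _ in poly.points]
        assert max(xs) - min(xs) >= 1.0

    def test_hidden_style_emits_nothing(self):
        feat = Feature(ftype="CDS", segments=[(0, 100)], strand=1)
        rec = _rec("A", 1000, [feat])
        layout = _layout([rec])
        import dataclasses

        style = dataclasses.replace(default_style(), hidden=True)
        assert feature_glyph(feat, style, layout, rec) == []

    def test_glyphs_never_overflow_their_sequence_extent(self, demo_records):
        layout = _layout(demo_records)
        for rec in demo_records:
            lo = layout.x_px(rec.record_id, 0) - 0.51
            hi = layout.x_px(rec.record_id, rec.length_bp) + 0.51
            for feat in rec.features:
                for prim in feature_glyph(feat, default_style(), layout, rec):
                    if isinstance(prim, Polygon):
                        assert all(lo <= x <= hi for x, _ in prim.points)

    def test_reverse_complement_display_mirrors_feature_positions(self):
        feat = Feature(ftype="CDS", segments=[(0, 1000)], strand=1)
        rec = _rec("A", 10000, [feat])
        rec.display_options.reverse_complement = True
        layout = _layout([rec])
        (poly,) = feature_glyph(feat, default_style(), layout, rec)
        xs = [x for x, _ in poly.points]
        # leftmost kb flips to the rightmost kb, head now points left
        assert min(xs) == pytest.approx(layout.x_px("A", 9000))
        assert (min(xs), layout.y_centers["A"]) in poly.points


class TestRibbon:
    def test_direct_hit_edges_project_the_intervals(self):
        records = [_rec("A", 10000), _rec("B", 10000)]
        layout = _layout(records)
        hit = _hit("A", "B", 1000, 2000, 3000, 4000)
        poly = ribbon(hit, layout, RibbonStyle())
        (x1, _), (x2, _), (x3, _), (x4, _) = poly.points
        assert (x1, x2) == (
            pytest.approx(layout.x_px("A", 1000)),
            pytest.approx(layout.x_px("A", 2000)),
        )
        assert {round(x3), round(x4)} == {
            round(layout.x_px("B", 4000)),
            round(layout.x_px("B", 3000)),
        }

    def test_inverted_hit_crosses_the_side_edges(self):
        records = [_rec("A", 10000), _rec("B", 10000)]
        layout = _layout(records)
        direct = ribbon(_hit("A", "B", 0, 1000, 0, 1000), layout, RibbonStyle())
        crossed = ribbon(
            _hit("A", "B", 0, 1000, 0, 1000, inverted=True), layout, RibbonStyle()
        )
        # direct: bottom edge runs right-to-left (closing the trapezoid);
        # inverted: bottom edge starts at the *left* subject corner
        assert direct.points[2][0] > direct.points[3][0]
        assert crossed.points[2][0] < crossed.points[3][0]

    def test_hit_touching_unknown_or_hidden_record_is_skipped(self):
        records = [_rec("A", 10000), _rec("B", 10000)]
        layout = _layout(records)
        assert ribbon(_hit("A", "Z", 0, 10, 0, 10), layout, RibbonStyle()) is None

    def test_ramp_endpoints(self):
        style = RibbonStyle(
            color_min="#000000", color_max="#ffffff", min_identity=60.0
        )
        assert identity_color(60.0, style) == "#000000"
        assert identity_color(100.0, style) == "#ffffff"

    def test_ramp_is_monotone_per_channel(self):
        style = RibbonStyle(
            color_min="#102030", color_max="#e0f0ff", min_identity=50.0
        )
        previous = (0, 0, 0)
        for identity in range(50, 101, 5):
            hexcolor = identity_color(float(identity), style)
            channels = tuple(int(hexcolor[i : i + 2], 16) for i in (1, 3, 5))
            assert all(c >= p for c, p in zip(channels, previous))
            previous = channels

    def test_distinct_inverted_color_mode(self):
        style = RibbonStyle(inverted_color="#ff0000")
        records = [_rec("A", 1000), _rec("B", 1000)]
        layout = _layout(records)
        poly = ribbon(_hit("A", "B", 0, 100, 0, 100, inverted=True), layout, style)
        assert poly.fill == "#ff0000"


class TestSvgOutput:
    def _demo_doc(self, demo_records):
        from genodraw.cli import demo_project
        from genodraw.pipeline import build_render_input

        # build a self-contained render input from already-parsed records
        from genodraw.render import RenderInput
        from genodraw.homology import builtin_search

        hits = {
            ("DEMO01", "DEMO02"): builtin_search(demo_records[0], demo_records[1]),
        }
        layout = build_layout(demo_records, hits, positioning="best_blast")
        cascade = [
            FeatureSpec(
                label="transposase",
                filter="transposase|tnp[ABC]",
                style=PartialStyle(fill_color="pink"),
            ),
            FeatureSpec(
                label="IS431",
                filter="IS431",
                field="product",
                style=PartialStyle(hatching="diagonal"),
            ),
        ]
        return RenderInput(
            records=demo_records,
            cascade=cascade,
            defaults=default_style(),
            draw_unmatched=True,
            hits_by_pair=hits,
            layout=layout,
        )

    def test_svg_is_wellformed_xml_with_svg_namespace(self, demo_records):
        text = svg_text(render_figure(self._demo_doc(demo_records)))
        root = ET.fromstring(text)
        assert root.tag == "{http://www.w3.org/2000/svg}svg"

    def test_rendering_twice_is_byte_identical(self, demo_records, tmp_path):
        inp = self._demo_doc(demo_records)
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        write_svg(render_figure(inp), p1)
        write_svg(render_figure(inp), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_legend_has_one_swatch_per_labelled_spec(self, demo_records):
        inp = self._demo_doc(demo_records)
        text = svg_text(render_figure(inp))
        root = ET.fromstring(text)
        ns = {"svg": "http://www.w3.org/2000/svg"}
        labels = [t.text for t in root.findall("svg:text", ns)]
        assert "transposase" in labels and "IS431" in labels
        # the transposase swatch carries the spec's pink fill
        pink = normalize_color("pink")
        swatches = [
            p
            for p in root.findall("svg:polygon", ns)
            if p.get("fill") == pink and len(p.get("points").split()) == 4
        ]
        assert swatches

    def test_hiding_a_sequence_removes_its_artwork_and_rescales(self, demo_records):
        inp = self._demo_doc(demo_records)
        full = svg_text(render_figure(inp))
        longest = max(demo_records, key=lambda r: r.length_bp)
        longest.active = False
        # rebuild with the sequence hidden
        from genodraw.render import RenderInput

        layout = build_layout(demo_records, inp.hits_by_pair)
        inp_hidden = RenderInput(
            records=demo_records,
            cascade=inp.cascade,
            defaults=inp.defaults,
            draw_unmatched=True,
            hits_by_pair=inp.hits_by_pair,
            layout=layout,
        )
        hidden = svg_text(render_figure(inp_hidden))
        assert longest.record_id in full
        assert longest.record_id not in hidden
        assert layout.px_per_bp > inp.layout.px_per_bp  # rescaled upward

    def test_hatched_polygons_reference_an_emitted_pattern(self, demo_records):
        text = svg_text(render_figure(self._demo_doc(demo_records)))
        assert 'url(#hatch-diagonal-' in text
        assert "<pattern id=\"hatch-diagonal-" in text

    def test_named_colors_normalized_to_hex(self):
        assert normalize_color("pink") == "#ffc0cb"
        assert normalize_color("#ABC") == "#aabbcc"

    def test_text_content_is_xml_escaped(self):
        doc_prims = [TextLabel(0, 0, "a<b&c", anchor="start")]
        from genodraw.render import FigureDocument

        doc = FigureDocument(width=10, height=10, primitives=doc_prims)
        text = svg_text(doc)
        assert "a&lt;b&amp;c" in text
        ET.fromstring(text)

    def test_png_rasterization_writes_a_file(self, demo_records, tmp_path):
        doc = render_figure(self._demo_doc(demo_records))
        out = tmp_path / "fig.png"
        write_png(doc, out, dpi=60)
        assert out.stat().st_size > 1000
        assert out.read_bytes()[:8] == b"\x89PNG\r\n\x1a\n"
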