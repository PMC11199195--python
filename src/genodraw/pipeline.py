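"""End-to-end pipeline: project -> loaded sequences -> hits -> figure.

Thin glue between the configuration model and the computational
modules, shared by the CLI and by library callers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .config import Project
from .decorations import gc_content, gc_skew
from .errors import ConfigError
from .homology import HomologyHit, compute_homology, filter_hits
from .layout import build_layout
from .render import FigureDocument, RenderInput, render_figure
from .seqio import SequenceRecord, load_sequences

__all__ = [
    "load_project_sequences",
    "project_homology",
    "build_render_input",
    "render_project",
]


def load_project_sequences(project: Project) -> list[SequenceRecord]:
    """Materialize the sequence panel: parse files, apply per-entry options.

    An entry with a ``record_id`` selects that single record from its
    file; otherwise every record in the file is included, in file
    order.  Display order equals panel (entry) order.
    """
    out: list[SequenceRecord] = []
    for entry in project.sequences:
        records = load_sequences(entry.path)
        if entry.record_id is not None:
            matches = [r for r in records if r.record_id == entry.record_id]
            if not matches:
                raise ConfigError(
                    f"record {entry.record_id!r} not found in {entry.path} "
                    f"(available: {', '.join(r.record_id for r in records)})"
                )
            records = matches
        for rec in records:
            rec.active = entry.active
            rec.display_options = dataclasses.replace(entry.display)
            if entry.display_name and len(records) == 1:
                rec.display_name = entry.display_name
            out.append(rec)
    seen: set[str] = set()
    for rec in out:
        if rec.record_id in seen:
            raise ConfigError(
                f"duplicate record id {rec.record_id!r} in the sequence panel"
            )
        seen.add(rec.record_id)
    return out


def project_homology(
    project: Project, records: list[SequenceRecord]
) -> dict[tuple[str, str], list[HomologyHit]]:
    """Raw hits per selected pair (cached), then threshold filtering."""
    raw = compute_homology(records, project.homology)
    return {pair: filter_hits(hits, project.homology) for pair, hits in raw.items()}


def build_render_input(
    project: Project,
    records: list[SequenceRecord] | None = None,
    hits_by_pair: dict[tuple[str, str], list[HomologyHit]] | None = None,
) -> RenderInput:
    """Resolve layout, decoration profiles, and styles for rendering."""
    if records is None:
        records = load_project_sequences(project)
    active = [r for r in records if r.active]
    if hits_by_pair is None:
        hits_by_pair = project_homology(project, records) if len(active) > 1 else {}

    decorations_per_record: dict[str, list[tuple[int, float, str]]] = {}
    for idx, deco in enumerate(project.decorations):
        for rec in active:
            if deco.applies_to(rec.record_id):
                decorations_per_record.setdefault(rec.record_id, []).append(
                    (idx, deco.track_height_px, deco.placement)
                )

    manual = {
        rec.record_id: entry.manual_offset_bp
        for entry, rec in _entry_record_pairs(project, records)
    }
    layout = build_layout(
        records,
        hits_by_pair,
        canvas_width=project.canvas.width,
        margin=project.canvas.margin,
        sequence_spacing=project.canvas.sequence_spacing,
        lane_height=project.canvas.lane_height,
        positioning=project.canvas.positioning,
        manual_offsets_bp=manual,
        decorations_per_record=decorations_per_record,
    )

    profiles = {}
    by_id = {r.record_id: r for r in active}
    for box in layout.track_boxes:
        deco = project.decorations[box.decoration_index]
        if deco.kind == "scale_bar":
            continue
        rec = by_id[box.record_id]
        fn = gc_content if deco.kind == "gc_content" else gc_skew
        profiles[(box.record_id, box.decoration_index)] = fn(
            rec, deco.window_bp, deco.step_bp
        )

    ribbon_style = dataclasses.replace(
        project.ribbon, min_identity=project.homology.min_identity
    )
    return RenderInput(
        records=records,
        cascade=project.features.cascade,
        defaults=project.features.defaults,
        draw_unmatched=project.features.draw_unmatched,
        hits_by_pair=hits_by_pair,
        layout=layout,
        decorations=project.decorations,
        profiles=profiles,
        ribbon_style=ribbon_style,
        legend=project.legend,
    )


def _entry_record_pairs(project: Project, records: list[SequenceRecord]):
    """Pair each loaded record back with the panel entry that produced it."""
    by_file: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        by_file.setdefault(rec.source_file or "", []).append(rec)
    for entry in project.sequences:
        resolved = str(Path(entry.path))
        for rec in records:
            if rec.source_file == resolved and (
                entry.record_id is None or rec.record_id == entry.record_id
            ):
                yield entry, rec


def render_project(project: Project) -> FigureDocument:
    """Full pipeline: load, search, lay out, and assemble the figure."""
    return render_figure(build_render_input(project))
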