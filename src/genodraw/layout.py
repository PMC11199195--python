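"""Figure geometry: global scale, horizontal offsets, vertical tracks.

Every sequence is drawn on the same bp-to-pixel scale, fixed by the
longest *active* sequence filling the drawable width.  Horizontal
placement is left-aligned by default, can use per-sequence manual
offsets, or the "best blast" mode: each sequence is shifted so that the
midpoint of its largest surviving hit against the sequence drawn above
it sits on the same vertical axis as the matching interval there.
Vertical placement stacks sequences in panel order, reserving extra
room for decoration tracks above/below individual sequences.  Layout is
a pure function of its inputs; repeated calls give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import LayoutError
from .homology import HomologyHit
from .seqio import SequenceRecord

__all__ = [
    "TrackBox",
    "LayoutModel",
    "compute_scale",
    "best_blast_offsets",
    "vertical_layout",
    "build_layout",
]

_TRACK_GAP_PX = 4.0  # breathing room between a track and its sequence lane


@dataclass(frozen=True)
class TrackBox:
    """Reserved vertical band for one decoration track of one sequence."""

    record_id: str
    decoration_index: int
    y_top: float
    height: float
    placement: str  # above | below


@dataclass
class LayoutModel:
    """Pixels-per-bp scale plus per-sequence x-offsets and y-centers."""

    px_per_bp: float
    canvas_width: float
    canvas_height: float
    margin: float
    lane_height: float
    x_offsets: dict[str, float] = field(default_factory=dict)
    y_centers: dict[str, float] = field(default_factory=dict)
    track_boxes: list[TrackBox] = field(default_factory=list)

    def x_px(self, record_id: str, bp: float) -> float:
        """Canvas x-coordinate of a base position on a given sequence."""
        return self.margin + self.x_offsets[record_id] + bp * self.px_per_bp


def compute_scale(
    active_records: list[SequenceRecord], drawable_width_px: float
) -> float:
    """px/bp so the longest active sequence spans the drawable width."""
    lengths = [r.length_bp for r in active_records if r.active]
    if not lengths:
        raise LayoutError("no active sequences: nothing to lay out")
    if drawable_width_px <= 0:
        raise LayoutError(f"drawable width must be positive, got {drawable_width_px}")
    return drawable_width_px / max(lengths)


def _hits_between(
    prev_id: str,
    cur_id: str,
    hits_by_pair: dict[tuple[str, str], list[HomologyHit]],
) -> list[tuple[HomologyHit, bool]]:
    """Hits linking two records, tagged with whether prev is the query."""
    tagged: list[tuple[HomologyHit, bool]] = []
    for h in hits_by_pair.get((prev_id, cur_id), []):
        tagged.append((h, True))
    for h in hits_by_pair.get((cur_id, prev_id), []):
        tagged.append((h, False))
    return tagged


def best_blast_offsets(
    active_records: list[SequenceRecord],
    hits_by_pair: dict[tuple[str, str], list[HomologyHit]],
    px_per_bp: float,
) -> dict[str, float]:
    """Chained anchor alignment on the largest hit to each predecessor.

    The first sequence starts at offset 0.  Each subsequent sequence
    anchors on the hit of maximal aligned length against its
    predecessor (ties: higher bitscore, then smaller query start) and is
    shifted so the two anchor-interval midpoints share a vertical axis;
    midpoints — rather than starts — keep the rule symmetric for
    inverted hits.  A sequence with no surviving hit to its predecessor
    inherits the predecessor's offset.  Finally all offsets are
    translated so the minimum is 0.
    """
    records = [r for r in active_records if r.active]
    if not records:
        raise LayoutError("no active sequences: nothing to lay out")
    offsets: dict[str, float] = {records[0].record_id: 0.0}
    for prev, cur in zip(records, records[1:]):
        base = offsets[prev.record_id]
        tagged = _hits_between(prev.record_id, cur.record_id, hits_by_pair)
        if not tagged:
            offsets[cur.record_id] = base
            continue
        hit, prev_is_query = max(
            tagged,
            key=lambda t: (t[0].align_length, t[0].bitscore, -t[0].q_start),
        )
        if prev_is_query:
            prev_mid = (hit.q_start + hit.q_end) / 2.0
            cur_mid = (hit.s_start + hit.s_end) / 2.0
        else:
            prev_mid = (hit.s_start + hit.s_end) / 2.0
            cur_mid = (hit.q_start + hit.q_end) / 2.0
        offsets[cur.record_id] = base + (prev_mid - cur_mid) * px_per_bp
    shift = min(offsets.values())
    return {rid: off - shift for rid, off in offsets.items()}


def vertical_layout(
    active_records: list[SequenceRecord],
    decorations_per_record: dict[str, list[tuple[int, float, str]]],
    sequence_spacing: float,
    margin: float,
    lane_height: float,
) -> tuple[dict[str, float], list[TrackBox], float]:
    """Stack sequences top to bottom, reserving decoration-track bands.

    ``decorations_per_record`` maps record id to a list of
    (decoration_index, height_px, placement) tuples.  Returns
    (y_centers, track_boxes, canvas_height); the height is derived from
    content, never fixed.
    """
    records = [r for r in active_records if r.active]
    if not records:
        raise LayoutError("no active sequences: nothing to lay out")
    y_centers: dict[str, float] = {}
    boxes: list[TrackBox] = []
    y = margin
    for rec in records:
        decos = decorations_per_record.get(rec.record_id, [])
        above = [(i, h) for i, h, place in decos if place == "above"]
        below = [(i, h) for i, h, place in decos if place == "below"]
        for idx, h in above:
            boxes.append(TrackBox(rec.record_id, idx, y, h, "above"))
            y += h + _TRACK_GAP_PX
        y_centers[rec.record_id] = y + lane_height / 2.0
        y += lane_height
        for idx, h in below:
            y += _TRACK_GAP_PX
            boxes.append(TrackBox(rec.record_id, idx, y, h, "below"))
            y += h
        y += sequence_spacing
    canvas_height = y - sequence_spacing + margin
    return y_centers, boxes, canvas_height


def build_layout(
    records: list[SequenceRecord],
    hits_by_pair: dict[tuple[str, str], list[HomologyHit]],
    canvas_width: float = 1200.0,
    margin: float = 40.0,
    sequence_spacing: float = 90.0,
    lane_height: float = 18.0,
    positioning: str = "left",
    manual_offsets_bp: dict[str, float] | None = None,
    decorations_per_record: dict[str, list[tuple[int, float, str]]] | None = None,
) -> LayoutModel:
    """Assemble the full layout model for the active sequences."""
    active = [r for r in records if r.active]
    drawable = canvas_width - 2 * margin
    px_per_bp = compute_scale(active, drawable)
    if positioning == "best_blast":
        x_offsets = best_blast_offsets(active, hits_by_pair, px_per_bp)
    elif positioning == "manual":
        raw = {
            r.record_id: (manual_offsets_bp or {}).get(r.record_id, 0.0) * px_per_bp
            for r in active
        }
        shift = min(raw.values())
        x_offsets = {rid: off - shift for rid, off in raw.items()}
    elif positioning == "left":
        x_offsets = {r.record_id: 0.0 for r in active}
    else:
        raise LayoutError(f"unknown positioning mode {positioning!r}")
    y_centers, boxes, canvas_height = vertical_layout(
        active,
        decorations_per_record or {},
        sequence_spacing,
        margin,
        lane_height,
    )
    return LayoutModel(
        px_per_bp=px_per_bp,
        canvas_width=canvas_width,
        canvas_height=canvas_height,
        margin=margin,
        lane_height=lane_height,
        x_offsets=x_offsets,
        y_centers=y_centers,
        track_boxes=boxes,
    )
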