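"""Sequence-composition decoration tracks: GC content, GC-skew, scale bars.

GC content is (G+C)/(A+C+G+T) per sliding window; GC-skew is the
standard (G-C)/(G+C), whose sign changes often mark the replication
origin and terminus in prokaryotic replicons.  Ambiguity codes are
excluded from both counts so N-runs in draft assemblies do not bias the
profile; a window with no unambiguous base yields 0 and is flagged as a
gap.  Profiles are computed on the *displayed* orientation of a
sequence so the track lines up with the drawing even when a sequence is
shown reverse-complemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .seqio import SequenceRecord

__all__ = [
    "DecorationSpec",
    "Profile",
    "ScaleBar",
    "gc_content",
    "gc_skew",
    "scale_bar_model",
]

KINDS = ("gc_content", "gc_skew", "scale_bar")


@dataclass
class DecorationSpec:
    """One decoration track: what to draw, where, and for which sequences."""

    kind: str
    window_bp: int = 1000
    step_bp: int = 100
    track_height_px: float = 40.0
    color_above: str = "#5050a0"
    color_below: str = "#c0c0e8"
    scope: str | list[str] = "all"  # "all" or explicit record ids
    placement: str = "above"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigError(f"unknown decoration kind {self.kind!r}")
        if self.window_bp <= 0 or self.step_bp <= 0:
            raise ConfigError("decoration window and step must be positive")
        if self.step_bp > self.window_bp:
            raise ConfigError(
                f"decoration step ({self.step_bp}) must not exceed the window "
                f"({self.window_bp})"
            )
        if self.placement not in ("above", "below"):
            raise ConfigError(f"unknown decoration placement {self.placement!r}")

    def applies_to(self, record_id: str) -> bool:
        return self.scope == "all" or record_id in self.scope


@dataclass
class Profile:
    """A per-window value series along one sequence.

    ``positions`` are window-center coordinates in bp, strictly
    increasing; ``gaps`` flags windows with no countable base.
    """

    record_id: str
    kind: str
    positions: list[float]
    values: list[float]
    gaps: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must have equal length")


def _window_starts(length: int, window: int, step: int) -> list[tuple[int, int]]:
    """Full windows at the given stride, plus a trailing partial window
    when at least half a window of sequence remains uncovered."""
    spans = [(i, i + window) for i in range(0, length - window + 1, step)]
    tail = spans[-1][0] + step if spans else 0
    if tail < length and length - tail >= window / 2:
        spans.append((tail, length))
    return spans


def _base_indicators(residues: str) -> dict[str, np.ndarray]:
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    out = {}
    for base in "ACGT":
        ind = (arr == ord(base)).astype(np.int64)
        out[base] = np.concatenate([[0], np.cumsum(ind)])
    return out


def _profile(
    record: SequenceRecord, window_bp: int, step_bp: int, kind: str
) -> Profile:
    residues = record.oriented_residues()
    length = len(residues)
    if window_bp > length:
        raise ConfigError(
            f"window ({window_bp} bp) longer than sequence "
            f"{record.record_id!r} ({length} bp)"
        )
    if step_bp <= 0 or step_bp > window_bp:
        raise ConfigError("step must satisfy 0 < step <= window")
    cum = _base_indicators(residues)
    positions: list[float] = []
    values: list[float] = []
    gaps: list[bool] = []
    for lo, hi in _window_starts(length, window_bp, step_bp):
        counts = {b: int(cum[b][hi] - cum[b][lo]) for b in "ACGT"}
        g, c = counts["G"], counts["C"]
        if kind == "gc_content":
            denom = sum(counts.values())
            value = (g + c) / denom if denom else 0.0
            gap = denom == 0
        else:  # gc_skew
            value = (g - c) / (g + c) if g + c else 0.0
            gap = g + c == 0
        positions.append(lo + (hi - lo) / 2.0)
        values.append(value)
        gaps.append(gap)
    return Profile(record.record_id, kind, positions, values, gaps)


def gc_content(record: SequenceRecord, window_bp: int, step_bp: int) -> Profile:
    """Sliding-window GC fraction in [0, 1] (ambiguity codes excluded)."""
    return _profile(record, window_bp, step_bp, "gc_content")


def gc_skew(record: SequenceRecord, window_bp: int, step_bp: int) -> Profile:
    """Sliding-window (G-C)/(G+C) in [-1, 1]; 0 where G+C is zero."""
    return _profile(record, window_bp, step_bp, "gc_skew")


@dataclass(frozen=True)
class ScaleBar:
    """Tick positions (bp) and formatted labels for one ruler."""

    interval_bp: int
    ticks_bp: tuple[int, ...]
    labels: tuple[str, ...]


def _format_bp(value: int) -> str:
    if value >= 1000 and value % 100 == 0:
        kb = value / 1000
        return f"{kb:g} kb"
    return f"{value} bp"


def scale_bar_model(length_bp: int, tick_target_count: int = 5) -> ScaleBar:
    """Ruler with a 1-2-5 x 10^k tick interval closest to the target count.

    Candidate intervals are {1, 2, 5} x 10^k; the one whose tick count
    (ticks at 0, i, 2i, ... <= length) is nearest ``tick_target_count``
    wins, ties going to the coarser interval.
    """
    if length_bp <= 0:
        raise ConfigError("scale bar needs a positive sequence length")
    best: tuple[float, float, int] | None = None
    for k in range(0, 10):
        for mult in (1, 2, 5):
            interval = mult * 10**k
            count = length_bp // interval + 1
            key = (abs(count - tick_target_count), -interval, interval)
            if best is None or key < best:
                best = key
    interval = best[2]
    ticks = tuple(range(0, length_bp + 1, interval))
    return ScaleBar(interval, ticks, tuple(_format_bp(t) for t in ticks))
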