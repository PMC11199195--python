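"""Regex-driven feature style cascade.

Each drawn feature gets its style from an ordered list of *feature
specifications*.  A spec selects features by type scope and by an
unanchored regular-expression search over one qualifier field (gene,
product, locus_tag, note) or over every qualifier value (``any``), and
carries a *partial* style: only the properties it sets.  Resolution
starts from a fully-set default style and applies matching specs in list
order, so later specs override earlier ones property by property —
"more specific" simply means "later in the list".  Typical use: one
broad spec colouring all transposases (filter ``transposase|tnp[ABC]``
in field ``any``) followed by a narrower one adding diagonal hatching to
a single IS family (filter ``IS431`` in field ``product``).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, replace

from .errors import ConfigError
from .seqio import Feature

__all__ = [
    "STYLE_PROPERTIES",
    "QUALIFIER_FIELDS",
    "PartialStyle",
    "FeatureSpec",
    "ResolvedStyle",
    "default_style",
    "match_spec",
    "resolve_style",
]

#: the eight overridable drawing properties, in declaration order
STYLE_PROPERTIES = (
    "fill_color",
    "outline_color",
    "outline_width",
    "shape",
    "height",
    "hatching",
    "label_visible",
    "label_text_source",
)

#: qualifier fields a spec may target ("any" searches every qualifier value)
QUALIFIER_FIELDS = ("gene", "product", "locus_tag", "note", "any")

SHAPES = ("arrow", "box", "pointer")
HATCHINGS = ("none", "diagonal", "horizontal", "vertical", "cross")


@dataclass(frozen=True)
class PartialStyle:
    """A style where each property is either set or ``None`` (unset)."""

    fill_color: str | None = None
    outline_color: str | None = None
    outline_width: float | None = None
    shape: str | None = None
    height: float | None = None
    hatching: str | None = None
    label_visible: bool | None = None
    label_text_source: str | None = None

    def set_properties(self) -> tuple[str, ...]:
        return tuple(p for p in STYLE_PROPERTIES if getattr(self, p) is not None)

    def __post_init__(self) -> None:
        if self.shape is not None and self.shape not in SHAPES:
            raise ConfigError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        if self.hatching is not None and self.hatching not in HATCHINGS:
            raise ConfigError(
                f"unknown hatching {self.hatching!r}; expected one of {HATCHINGS}"
            )


@dataclass(frozen=True)
class ResolvedStyle:
    """A fully-set style, plus which cascade positions contributed."""

    fill_color: str
    outline_color: str
    outline_width: float
    shape: str
    height: float
    hatching: str
    label_visible: bool
    label_text_source: str
    matched_spec_indices: tuple[int, ...] = ()
    hidden: bool = False


def default_style() -> ResolvedStyle:
    """Neutral defaults: grey strand-oriented arrows, no hatching, no label."""
    return ResolvedStyle(
        fill_color="#c8c8c8",
        outline_color="#000000",
        outline_width=1.0,
        shape="arrow",
        height=14.0,
        hatching="none",
        label_visible=False,
        label_text_source="gene",
    )


@dataclass
class FeatureSpec:
    """One ordered entry of the style cascade.

    ``filter`` is a regular expression searched (unanchored) in the
    values of ``field``; an empty filter matches every feature in scope.
    Matching is case-insensitive unless ``case_sensitive`` is set —
    annotation capitalization is too inconsistent across pipelines to
    rely on.  ``draw=False`` suppresses drawing of every match.
    """

    label: str = ""
    ftype_scope: str = "any"
    filter: str = ""
    field: str = "any"
    style: PartialStyle = dataclasses.field(default_factory=PartialStyle)
    draw: bool = True
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.field not in QUALIFIER_FIELDS:
            raise ConfigError(
                f"feature spec {self.label or self.filter!r}: unknown field "
                f"{self.field!r}; expected one of {QUALIFIER_FIELDS}"
            )
        flags = 0 if self.case_sensitive else re.IGNORECASE
        try:
            self._compiled = re.compile(self.filter, flags)
        except re.error as exc:
            raise ConfigError(
                f"feature spec {self.label or self.filter!r}: invalid regular "
                f"expression {self.filter!r}: {exc}"
            ) from exc
        if not self.style.set_properties() and self.draw:
            raise ConfigError(
                f"feature spec {self.label or self.filter!r} sets no style "
                f"property and does not hide its matches; it would do nothing"
            )

    @property
    def compiled(self) -> re.Pattern:
        return self._compiled


def match_spec(feature: Feature, spec: FeatureSpec) -> bool:
    """True iff the feature is in the spec's type scope and the filter hits.

    An empty filter matches every in-scope feature; otherwise the regex
    is searched in each value of the designated qualifier field (all
    qualifier values for ``field='any'``).
    """
    if spec.ftype_scope not in ("any", feature.ftype):
        return False
    if not spec.filter:
        return True
    return any(spec.compiled.search(v) for v in feature.qualifier_values(spec.field))


def resolve_style(
    feature: Feature,
    cascade: list[FeatureSpec],
    defaults: ResolvedStyle | None = None,
) -> ResolvedStyle:
    """Fold the cascade over one feature: property-wise last-writer-wins.

    Starting from ``defaults``, every matching spec overwrites exactly
    the properties it sets; untouched properties keep the default value.
    Any matching spec with ``draw=False`` marks the feature hidden.
    Pure function: no inputs are mutated.
    """
    resolved = defaults if defaults is not None else default_style()
    matched: list[int] = []
    hidden = False
    updates: dict[str, object] = {}
    for idx, spec in enumerate(cascade):
        if not match_spec(feature, spec):
            continue
        matched.append(idx)
        if not spec.draw:
            hidden = True
        for prop in spec.style.set_properties():
            updates[prop] = getattr(spec.style, prop)
    return replace(
        resolved,
        **updates,
        matched_spec_indices=tuple(matched),
        hidden=hidden,
    )
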