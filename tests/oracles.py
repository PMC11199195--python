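"""Independent brute-force oracles used by the tests.

These deliberately re-derive expected results by the most direct method
available (re-evaluation, enumeration, recounting) without calling the
code paths they check.
"""

from __future__ import annotations

import re

import numpy as np

from genodraw.featurestyle import (
    HATCHINGS,
    QUALIFIER_FIELDS,
    SHAPES,
    STYLE_PROPERTIES,
    FeatureSpec,
    PartialStyle,
)
from genodraw.seqio import Feature


def spec_matches(feature: Feature, spec: FeatureSpec) -> bool:
    """Direct re-evaluation of the matching predicate."""
    if spec.ftype_scope != "any" and spec.ftype_scope != feature.ftype:
        return False
    if spec.filter == "":
        return True
    if spec.field == "any":
        values = [v for vs in feature.qualifiers.values() for v in vs]
    else:
        values = feature.qualifiers.get(spec.field, [])
    flags = 0 if spec.case_sensitive else re.IGNORECASE
    return any(re.search(spec.filter, v, flags) for v in values)


def resolve_brute_force(feature, cascade, defaults) -> dict:
    """Property-wise last-writer-wins, evaluated per property.

    For each style property, scan the cascade from the END and take the
    first matching spec that sets it; fall back to the default.
    """
    out = {}
    for prop in STYLE_PROPERTIES:
        value = getattr(defaults, prop)
        for spec in reversed(cascade):
            if spec_matches(feature, spec) and getattr(spec.style, prop) is not None:
                value = getattr(spec.style, prop)
                break
        out[prop] = value
    out["hidden"] = any(
        not spec.draw for spec in cascade if spec_matches(feature, spec)
    )
    out["matched_spec_indices"] = tuple(
        i for i, spec in enumerate(cascade) if spec_matches(feature, spec)
    )
    return out


# vocabulary for randomized cascade/feature generation
_WORDS = ["transposase", "tnpA", "tnpB", "integrase", "hypothetical", "mecA", "IS431"]
_FILTERS = ["", "transposase", "tnp[ABC]", "IS431", "mec.", "integrase|tnpA", "hyp"]
_COLORS = ["#ff0000", "#00ff00", "#0000ff", "#ffc0cb", "#808080"]


def random_feature(rng: np.random.Generator) -> Feature:
    quals = {}
    for field in ("gene", "product", "locus_tag", "note"):
        if rng.random() < 0.7:
            n = int(rng.integers(1, 3))
            quals[field] = [
                " ".join(rng.choice(_WORDS, size=int(rng.integers(1, 3))))
                for _ in range(n)
            ]
    ftype = str(rng.choice(["CDS", "tRNA", "repeat_region"]))
    start = int(rng.integers(0, 5000))
    return Feature(
        ftype=ftype,
        segments=[(start, start + int(rng.integers(50, 900)))],
        strand=int(rng.choice([1, -1, 0])),
        qualifiers=quals,
    )


def random_partial_style(rng: np.random.Generator) -> PartialStyle:
    props = {}
    n_set = int(rng.integers(1, len(STYLE_PROPERTIES) + 1))
    chosen = rng.choice(len(STYLE_PROPERTIES), size=n_set, replace=False)
    for idx in chosen:
        prop = STYLE_PROPERTIES[idx]
        if prop in ("fill_color", "outline_color"):
            props[prop] = str(rng.choice(_COLORS))
        elif prop in ("outline_width", "height"):
            props[prop] = float(np.round(rng.uniform(0.5, 20.0), 2))
        elif prop == "shape":
            props[prop] = str(rng.choice(SHAPES))
        elif prop == "hatching":
            props[prop] = str(rng.choice(HATCHINGS))
        elif prop == "label_visible":
            props[prop] = bool(rng.random() < 0.5)
        else:
            props[prop] = str(rng.choice(["gene", "product", "locus_tag"]))
    return PartialStyle(**props)


def random_cascade(rng: np.random.Generator, max_specs: int = 6) -> list[FeatureSpec]:
    n = int(rng.integers(0, max_specs + 1))
    cascade = []
    for _ in range(n):
        cascade.append(
            FeatureSpec(
                label="",
                ftype_scope=str(rng.choice(["any", "CDS", "tRNA"])),
                filter=str(rng.choice(_FILTERS)),
                field=str(rng.choice(QUALIFIER_FIELDS)),
                style=random_partial_style(rng),
                draw=bool(rng.random() < 0.9),
                case_sensitive=bool(rng.random() < 0.2),
            )
        )
    return cascade
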