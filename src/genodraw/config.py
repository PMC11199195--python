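"""Project and display-configuration files.

A *project* is the complete serializable state of one figure: the
sequence list (paths, order, activity, per-sequence display options),
the feature style cascade, homology settings, decorations, legend and
canvas settings.  Saving and reloading a project recreates the same
figure.  A *display configuration* is the portable subset — feature,
homology, legend, and decoration parameters only, with no file paths
and no record ids — meant to be applied to a different sequence set for
a consistent look across figures.

Both documents share one YAML format, discriminated by a top-level
``kind`` tag so they can never be confused silently.  Loading is
strict: unknown keys are rejected with their full key path.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .decorations import DecorationSpec
from .errors import ConfigError
from .featurestyle import (
    STYLE_PROPERTIES,
    FeatureSpec,
    PartialStyle,
    ResolvedStyle,
    default_style,
)
from .homology import HomologyConfig
from .render import LegendConfig, RibbonStyle
from .seqio import DisplayOptions

__all__ = [
    "FORMAT_VERSION",
    "CanvasConfig",
    "SequenceEntry",
    "FeatureConfig",
    "ScaleConfig",
    "Project",
    "save_project",
    "load_project",
    "export_display_config",
    "apply_display_config",
]

FORMAT_VERSION = 1

_DISPLAY_GROUPS = ("features", "homology", "legend", "decorations")


@dataclass
class CanvasConfig:
    width: float = 1200.0
    margin: float = 40.0
    sequence_spacing: float = 90.0
    lane_height: float = 18.0
    positioning: str = "left"  # left | manual | best_blast

    def __post_init__(self) -> None:
        if self.positioning not in ("left", "manual", "best_blast"):
            raise ConfigError(f"unknown positioning mode {self.positioning!r}")
        if self.width <= 2 * self.margin:
            raise ConfigError("canvas width must exceed twice the margin")


@dataclass
class SequenceEntry:
    """One row of the sequence panel: a file (or one record of it)."""

    path: str
    record_id: str | None = None  # None: every record in the file
    display_name: str | None = None
    active: bool = True
    manual_offset_bp: float = 0.0
    display: DisplayOptions = field(default_factory=DisplayOptions)


@dataclass
class FeatureConfig:
    defaults: ResolvedStyle = field(default_factory=default_style)
    draw_unmatched: bool = True
    cascade: list[FeatureSpec] = field(default_factory=list)


@dataclass
class ScaleConfig:
    show: bool = True
    tick_target: int = 5


@dataclass
class Project:
    """Complete serializable figure state."""

    canvas: CanvasConfig = field(default_factory=CanvasConfig)
    sequences: list[SequenceEntry] = field(default_factory=list)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    homology: HomologyConfig = field(default_factory=HomologyConfig)
    ribbon: RibbonStyle = field(default_factory=RibbonStyle)
    decorations: list[DecorationSpec] = field(default_factory=list)
    legend: LegendConfig = field(default_factory=LegendConfig)
    scale: ScaleConfig = field(default_factory=ScaleConfig)
    format_version: int = FORMAT_VERSION


# ---------------------------------------------------------------------------
# strict dict -> dataclass conversion


def _check_keys(data: dict, allowed: tuple[str, ...], path: str) -> None:
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping at '{path}', got {type(data).__name__}")
    unknown = [k for k in data if k not in allowed]
    if unknown:
        raise ConfigError(
            f"unknown key '{path}.{unknown[0]}' (allowed: {', '.join(allowed)})"
        )


def _simple_from_dict(cls, data: dict, path: str):
    """Build a flat dataclass from a dict, strictly and with defaults."""
    names = tuple(f.name for f in dataclasses.fields(cls))
    _check_keys(data, names, path)
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"invalid value under '{path}': {exc}") from exc


def _simple_to_dict(obj) -> dict:
    return dataclasses.asdict(obj)


def _style_to_dict(style: PartialStyle) -> dict:
    return {p: getattr(style, p) for p in style.set_properties()}


def _style_from_dict(data: dict, path: str) -> PartialStyle:
    _check_keys(data, STYLE_PROPERTIES, path)
    return PartialStyle(**data)


def _spec_to_dict(spec: FeatureSpec) -> dict:
    return {
        "label": spec.label,
        "ftype_scope": spec.ftype_scope,
        "filter": spec.filter,
        "field": spec.field,
        "draw": spec.draw,
        "case_sensitive": spec.case_sensitive,
        "style": _style_to_dict(spec.style),
    }


_SPEC_KEYS = ("label", "ftype_scope", "filter", "field", "draw", "case_sensitive", "style")


def _spec_from_dict(data: dict, path: str) -> FeatureSpec:
    _check_keys(data, _SPEC_KEYS, path)
    kwargs = dict(data)
    kwargs["style"] = _style_from_dict(kwargs.get("style", {}) or {}, f"{path}.style")
    return FeatureSpec(**kwargs)


def _defaults_to_dict(style: ResolvedStyle) -> dict:
    return {p: getattr(style, p) for p in STYLE_PROPERTIES}


def _defaults_from_dict(data: dict, path: str) -> ResolvedStyle:
    _check_keys(data, STYLE_PROPERTIES, path)
    return replace(default_style(), **data)


def _features_to_dict(cfg: FeatureConfig) -> dict:
    return {
        "defaults": _defaults_to_dict(cfg.defaults),
        "draw_unmatched": cfg.draw_unmatched,
        "cascade": [_spec_to_dict(s) for s in cfg.cascade],
    }


def _features_from_dict(data: dict, path: str) -> FeatureConfig:
    _check_keys(data, ("defaults", "draw_unmatched", "cascade"), path)
    cascade_raw = data.get("cascade", [])
    if not isinstance(cascade_raw, list):
        raise ConfigError(f"'{path}.cascade' must be a list")
    return FeatureConfig(
        defaults=_defaults_from_dict(data.get("defaults", {}) or {}, f"{path}.defaults"),
        draw_unmatched=bool(data.get("draw_unmatched", True)),
        cascade=[
            _spec_from_dict(s, f"{path}.cascade[{i}]")
            for i, s in enumerate(cascade_raw)
        ],
    )


def _sequences_from_list(data: list, path: str) -> list[SequenceEntry]:
    entries = []
    for i, item in enumerate(data):
        ipath = f"{path}[{i}]"
        _check_keys(
            item,
            ("path", "record_id", "display_name", "active", "manual_offset_bp", "display"),
            ipath,
        )
        if "path" not in item:
            raise ConfigError(f"sequence entry '{ipath}' is missing 'path'")
        kwargs = dict(item)
        kwargs["display"] = _simple_from_dict(
            DisplayOptions, kwargs.get("display", {}) or {}, f"{ipath}.display"
        )
        entries.append(SequenceEntry(**kwargs))
    return entries


_HOMOLOGY_DISPLAY_KEYS = (
    "program",
    "min_length",
    "min_identity",
    "max_evalue",
    "seed_length",
    "x_drop",
)
_HOMOLOGY_PROJECT_KEYS = _HOMOLOGY_DISPLAY_KEYS + (
    "pairing",
    "custom_pairs",
    "cache_path",
    "ribbon",
)


def _homology_to_dict(cfg: HomologyConfig, ribbon: RibbonStyle) -> dict:
    out = {k: getattr(cfg, k) for k in _HOMOLOGY_DISPLAY_KEYS}
    out["pairing"] = cfg.pairing
    out["custom_pairs"] = [list(p) for p in cfg.custom_pairs]
    out["cache_path"] = cfg.cache_path
    out["ribbon"] = _simple_to_dict(ribbon)
    return out


def _homology_from_dict(
    data: dict, path: str, display_only: bool
) -> tuple[HomologyConfig, RibbonStyle]:
    allowed = (
        _HOMOLOGY_DISPLAY_KEYS + ("ribbon",) if display_only else _HOMOLOGY_PROJECT_KEYS
    )
    _check_keys(data, allowed, path)
    kwargs = {k: v for k, v in data.items() if k != "ribbon"}
    ribbon = _simple_from_dict(
        RibbonStyle, data.get("ribbon", {}) or {}, f"{path}.ribbon"
    )
    return HomologyConfig(**kwargs), ribbon


def _decorations_from_list(data: list, path: str) -> list[DecorationSpec]:
    names = tuple(f.name for f in dataclasses.fields(DecorationSpec))
    out = []
    for i, item in enumerate(data):
        out.append(_simple_from_dict(DecorationSpec, item, f"{path}[{i}]"))
    return out


_TOP_KEYS_PROJECT = (
    "kind",
    "format_version",
    "canvas",
    "sequences",
    "features",
    "homology",
    "decorations",
    "legend",
    "scale",
)
_TOP_KEYS_DISPLAY = ("kind", "format_version") + _DISPLAY_GROUPS


def project_to_dict(project: Project) -> dict:
    return {
        "kind": "project",
        "format_version": project.format_version,
        "canvas": _simple_to_dict(project.canvas),
        "sequences": [
            {
                "path": e.path,
                "record_id": e.record_id,
                "display_name": e.display_name,
                "active": e.active,
                "manual_offset_bp": e.manual_offset_bp,
                "display": _simple_to_dict(e.display),
            }
            for e in project.sequences
        ],
        "features": _features_to_dict(project.features),
        "homology": _homology_to_dict(project.homology, project.ribbon),
        "decorations": [_simple_to_dict(d) for d in project.decorations],
        "legend": _simple_to_dict(project.legend),
        "scale": _simple_to_dict(project.scale),
    }


def project_from_dict(data: dict, path: str = "project") -> Project:
    _check_keys(data, _TOP_KEYS_PROJECT, path)
    kind = data.get("kind", "project")
    if kind == "display_config":
        raise ConfigError(
            "this file is a display configuration (kind: display_config), "
            "not a project; load it with apply_display_config"
        )
    if kind != "project":
        raise ConfigError(f"unknown document kind {kind!r}")
    version = int(data.get("format_version", FORMAT_VERSION))
    if version > FORMAT_VERSION:
        raise ConfigError(
            f"project format version {version} is newer than supported "
            f"({FORMAT_VERSION})"
        )
    homology, ribbon = _homology_from_dict(
        data.get("homology", {}) or {}, f"{path}.homology", display_only=False
    )
    return Project(
        canvas=_simple_from_dict(
            CanvasConfig, data.get("canvas", {}) or {}, f"{path}.canvas"
        ),
        sequences=_sequences_from_list(
            data.get("sequences", []) or [], f"{path}.sequences"
        ),
        features=_features_from_dict(
            data.get("features", {}) or {}, f"{path}.features"
        ),
        homology=homology,
        ribbon=ribbon,
        decorations=_decorations_from_list(
            data.get("decorations", []) or [], f"{path}.decorations"
        ),
        legend=_simple_from_dict(
            LegendConfig, data.get("legend", {}) or {}, f"{path}.legend"
        ),
        scale=_simple_from_dict(
            ScaleConfig, data.get("scale", {}) or {}, f"{path}.scale"
        ),
        format_version=version,
    )


# ---------------------------------------------------------------------------
# file I/O


def _dump_yaml(data: dict, path: Path) -> None:
    path.write_text(yaml.safe_dump(data, sort_keys=False, default_flow_style=False))


def _load_yaml(path: Path) -> dict:
    if not path.exists():
        raise ConfigError(f"configuration file {path} does not exist")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path} does not contain a configuration mapping")
    return data


def save_project(project: Project, path: str | Path) -> None:
    """Write the project as YAML; sequence paths become relative to it."""
    path = Path(path)
    base = path.resolve().parent
    doc = project_to_dict(project)
    for entry in doc["sequences"]:
        p = Path(entry["path"])
        if p.is_absolute():
            try:
                entry["path"] = os.path.relpath(p, base)
            except ValueError:  # different drive (windows); keep absolute
                pass
    _dump_yaml(doc, path)


def load_project(path: str | Path) -> Project:
    """Load and validate a project; sequence paths are resolved absolute.

    All referenced sequence files must exist; every missing path is
    reported in one error.
    """
    path = Path(path)
    project = project_from_dict(_load_yaml(path), path="project")
    base = path.resolve().parent
    missing = []
    for entry in project.sequences:
        resolved = Path(entry.path)
        if not resolved.is_absolute():
            resolved = Path(os.path.normpath(base / resolved))
        entry.path = str(resolved)
        if not resolved.exists():
            missing.append(str(resolved))
    if missing:
        raise ConfigError(
            "project references missing sequence files: " + ", ".join(missing)
        )
    return project


def display_config_to_dict(project: Project) -> dict:
    """The four portable groups, stripped of paths and record ids."""
    homology = {k: getattr(project.homology, k) for k in _HOMOLOGY_DISPLAY_KEYS}
    homology["ribbon"] = _simple_to_dict(project.ribbon)
    decorations = []
    for d in project.decorations:
        dd = _simple_to_dict(d)
        dd["scope"] = "all"  # record ids never travel in a display config
        decorations.append(dd)
    return {
        "kind": "display_config",
        "format_version": project.format_version,
        "features": _features_to_dict(project.features),
        "homology": homology,
        "legend": _simple_to_dict(project.legend),
        "decorations": decorations,
    }


def export_display_config(project: Project, path: str | Path) -> None:
    _dump_yaml(display_config_to_dict(project), Path(path))


def apply_display_config(path: str | Path, project: Project) -> Project:
    """Replace the four display groups of a project; all else untouched."""
    path = Path(path)
    data = _load_yaml(path)
    kind = data.get("kind")
    if kind == "project":
        raise ConfigError(
            "this file is a full project (kind: project), not a display "
            "configuration; load it with load_project"
        )
    if kind != "display_config":
        raise ConfigError(f"unknown document kind {kind!r}")
    _check_keys(data, _TOP_KEYS_DISPLAY, "display_config")
    display_homology, ribbon = _homology_from_dict(
        data.get("homology", {}) or {}, "display_config.homology", display_only=True
    )
    merged_homology = replace(
        project.homology,
        **{k: getattr(display_homology, k) for k in _HOMOLOGY_DISPLAY_KEYS},
    )
    return replace(
        project,
        features=_features_from_dict(
            data.get("features", {}) or {}, "display_config.features"
        ),
        homology=merged_homology,
        ribbon=ribbon,
        legend=_simple_from_dict(
            LegendConfig, data.get("legend", {}) or {}, "display_config.legend"
        ),
        decorations=_decorations_from_list(
            data.get("decorations", []) or [], "display_config.decorations"
        ),
    )
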