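"""JSON configuration parsing, normalization and validation.

A configuration holds an ordered list of annotation *queries* plus global
parameters (input paths, the ``priority`` flag, shared ``show.attributes``).
Each query is a conjunction of filters — feature types, an asymmetric
distance window around one or more feature anchors, strand/direction
constraints, an attribute filter — evaluated independently per peak.

Query keys accept either ``.`` or ``_`` separators (``feature.anchor`` and
``feature_anchor`` are equivalent) and scalar values are promoted to
one-element lists wherever a list is allowed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

__all__ = [
    "QuerySpec",
    "ConfigSpec",
    "Diagnostic",
    "ConfigError",
    "parse_config",
    "normalize_query",
    "validate_config",
    "serialize_config",
    "effective_show_attributes",
]

VALID_ANCHORS = ("start", "center", "end")
VALID_STRAND_MODES = ("ignore", "same", "opposite")
VALID_DIRECTIONS = ("any", "upstream", "downstream")

#: Default one-sided distance when a query gives none: permissive enough to
#: reproduce plain closest-feature behaviour on typical genomes.
DEFAULT_DISTANCE = 100_000

# canonical name -> accepted spellings (dots and underscores interchangeable)
_QUERY_KEYS = {
    "feature": ("feature", "features"),
    "feature_anchor": ("feature.anchor", "feature_anchor"),
    "distance": ("distance",),
    "strand": ("strand",),
    "direction": ("direction",),
    "internals": ("internals",),
    "filter_attribute": ("filter.attribute", "filter_attribute"),
    "attribute_value": ("attribute.value", "attribute_value"),
    "show_attributes": ("show.attributes", "show_attributes"),
}
_GLOBAL_KEYS = {
    "queries": ("queries",),
    "priority": ("priority",),
    "gtf": ("gtf",),
    "bed": ("bed",),
    "show_attributes": ("show.attributes", "show_attributes"),
}


class ConfigError(ValueError):
    """Raised for malformed or invalid configuration input."""


@dataclass
class QuerySpec:
    """One normalized annotation query.

    Attributes
    ----------
    index : int
        0-based position of the query in the configuration.
    features : list[str]
        Accepted feature types (GTF column 3); empty list = any type.
    distance_upstream, distance_downstream : int
        Maximum allowed distance (bp) of the peak center upstream /
        downstream of a feature anchor, in feature orientation.
    anchors : tuple[str, ...]
        Subset of ``("start", "center", "end")``; the closest requested
        anchor is used per feature.
    strand_mode : str
        ``ignore`` | ``same`` | ``opposite`` — peak-vs-feature strand rule.
    direction : str
        ``any`` | ``upstream`` | ``downstream`` — required location of the
        peak relative to the feature, in feature orientation.
    internals : bool
        Accept a peak centered inside a feature (or a feature contained in
        the peak) regardless of anchor distance.
    filter_attribute : str | None
        GTF attribute key to filter on (e.g. ``gene_biotype``).
    attribute_values : list[str]
        Accepted values for ``filter_attribute``.
    show_attributes : list[str]
        Attribute keys reported as extra output columns.
    """

    index: int = 0
    features: list[str] = field(default_factory=list)
    distance_upstream: int = DEFAULT_DISTANCE
    distance_downstream: int = DEFAULT_DISTANCE
    anchors: tuple[str, ...] = VALID_ANCHORS
    strand_mode: str = "ignore"
    direction: str = "any"
    internals: bool = False
    filter_attribute: str | None = None
    attribute_values: list[str] = field(default_factory=list)
    show_attributes: list[str] = field(default_factory=list)


@dataclass
class ConfigSpec:
    """A full parsed configuration: ordered queries plus global parameters."""

    queries: list[QuerySpec]
    priority: bool = False
    gtf_path: str | None = None
    bed_path: str | None = None
    global_show_attributes: list[str] = field(default_factory=list)


@dataclass
class Diagnostic:
    """A validation finding; ``fatal`` diagnostics should abort a run."""

    level: str  # "fatal" | "warning"
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.message}"


def _canonical(raw_key: str, table: dict[str, tuple[str, ...]]) -> str | None:
    for canon, spellings in table.items():
        if raw_key in spellings:
            return canon
    return None


def _as_list(value) -> list:
    if isinstance(value, (list, tuple)):
        return list(value)
    return [value]


def _as_bool(value, key: str, where: str) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str) and value.upper() in ("TRUE", "FALSE"):
        return value.upper() == "TRUE"
    raise ConfigError(f"{where}: key '{key}' expects true/false, got {value!r}")


def normalize_query(raw: dict, index: int) -> QuerySpec:
    """Normalize one raw query mapping into a :class:`QuerySpec`.

    Scalars are promoted to lists where lists are allowed, a scalar
    distance ``d`` expands to the symmetric window ``[d, d]``, and defaults
    are applied for absent keys. Unknown keys are fatal.
    """
    where = f"query {index}"
    canon: dict[str, object] = {}
    for key, value in raw.items():
        name = _canonical(key, _QUERY_KEYS)
        if name is None:
            raise ConfigError(f"{where}: unknown key '{key}'")
        canon[name] = value

    q = QuerySpec(index=index)

    if "feature" in canon:
        q.features = [str(v) for v in _as_list(canon["feature"])]

    if "distance" in canon:
        dist = canon["distance"]
        if isinstance(dist, (list, tuple)):
            if len(dist) == 1:
                up = down = int(dist[0])
            elif len(dist) == 2:
                up, down = int(dist[0]), int(dist[1])
            else:
                raise ConfigError(
                    f"{where}: distance list must have 1 or 2 elements, got {len(dist)}"
                )
        else:
            up = down = int(dist)
        if up < 0 or down < 0:
            raise ConfigError(f"{where}: distance must be non-negative, got {dist!r}")
        q.distance_upstream, q.distance_downstream = up, down

    if "feature_anchor" in canon:
        anchors = [str(a) for a in _as_list(canon["feature_anchor"])]
        for a in anchors:
            if a not in VALID_ANCHORS:
                raise ConfigError(
                    f"{where}: feature.anchor must be one of {VALID_ANCHORS}, got '{a}'"
                )
        # keep canonical start/center/end ordering, drop duplicates
        q.anchors = tuple(a for a in VALID_ANCHORS if a in anchors)

    if "strand" in canon:
        mode = str(canon["strand"]).lower()
        if mode not in VALID_STRAND_MODES:
            raise ConfigError(
                f"{where}: strand must be one of {VALID_STRAND_MODES}, got '{canon['strand']}'"
            )
        q.strand_mode = mode

    if "direction" in canon:
        direction = str(canon["direction"]).lower()
        if direction not in VALID_DIRECTIONS:
            raise ConfigError(
                f"{where}: direction must be one of {VALID_DIRECTIONS}, got '{canon['direction']}'"
            )
        q.direction = direction

    if "internals" in canon:
        q.internals = _as_bool(canon["internals"], "internals", where)

    if "filter_attribute" in canon:
        q.filter_attribute = str(canon["filter_attribute"])
    if "attribute_value" in canon:
        q.attribute_values = [str(v) for v in _as_list(canon["attribute_value"])]
    if q.attribute_values and q.filter_attribute is None:
        raise ConfigError(f"{where}: attribute.value given without filter.attribute")
    if q.filter_attribute is not None and not q.attribute_values:
        raise ConfigError(f"{where}: filter.attribute given without attribute.value")

    if "show_attributes" in canon:
        q.show_attributes = [str(v) for v in _as_list(canon["show_attributes"])]

    return q


def parse_config(json_text: str) -> ConfigSpec:
    """Parse a JSON configuration string into a normalized :class:`ConfigSpec`.

    Raises
    ------
    ConfigError
        On malformed JSON (naming the line), unknown keys (naming key and
        query index), or a missing ``queries`` entry.
    """
    try:
        data = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"malformed JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a JSON object")

    canon: dict[str, object] = {}
    for key, value in data.items():
        name = _canonical(key, _GLOBAL_KEYS)
        if name is None:
            raise ConfigError(f"unknown global key '{key}'")
        canon[name] = value

    if "queries" not in canon:
        raise ConfigError("configuration is missing the 'queries' list")
    raw_queries = canon["queries"]
    if not isinstance(raw_queries, list):
        raise ConfigError("'queries' must be a JSON array")

    queries = [normalize_query(raw, i) for i, raw in enumerate(raw_queries)]

    cfg = ConfigSpec(queries=queries)
    if "priority" in canon:
        cfg.priority = _as_bool(canon["priority"], "priority", "global")
    if "gtf" in canon:
        cfg.gtf_path = str(canon["gtf"])
    if "bed" in canon:
        cfg.bed_path = str(canon["bed"])
    if "show_attributes" in canon:
        cfg.global_show_attributes = [str(v) for v in _as_list(canon["show_attributes"])]
    return cfg


def effective_show_attributes(cfg: ConfigSpec) -> list[str]:
    """Union of global and per-query show-attributes, first-seen order."""
    seen: list[str] = []
    for key in cfg.global_show_attributes:
        if key not in seen:
            seen.append(key)
    for q in cfg.queries:
        for key in q.show_attributes:
            if key not in seen:
                seen.append(key)
    return seen


def serialize_config(cfg: ConfigSpec) -> str:
    """Emit a normalized configuration as JSON.

    ``parse_config(serialize_config(cfg))`` reproduces ``cfg`` exactly.
    """
    out: dict[str, object] = {"queries": []}
    for q in cfg.queries:
        entry: dict[str, object] = {
            "distance": [q.distance_upstream, q.distance_downstream],
            "feature_anchor": list(q.anchors),
            "strand": q.strand_mode,
            "direction": q.direction,
            "internals": q.internals,
        }
        if q.features:
            entry["feature"] = q.features
        if q.filter_attribute is not None:
            entry["filter_attribute"] = q.filter_attribute
            entry["attribute_value"] = q.attribute_values
        if q.show_attributes:
            entry["show_attributes"] = q.show_attributes
        out["queries"].append(entry)
    out["priority"] = cfg.priority
    if cfg.gtf_path is not None:
        out["gtf"] = cfg.gtf_path
    if cfg.bed_path is not None:
        out["bed"] = cfg.bed_path
    if cfg.global_show_attributes:
        out["show_attributes"] = cfg.global_show_attributes
    return json.dumps(out, indent=2)


def validate_config(cfg: ConfigSpec) -> list[Diagnostic]:
    """Check a parsed configuration; returns diagnostics, never raises.

    The caller decides fatality: any ``fatal``-level diagnostic should
    abort. Duplicate show-attribute keys are deduplicated in place with a
    warning.
    """
    diags: list[Diagnostic] = []
    if not cfg.queries:
        diags.append(Diagnostic("fatal", "configuration contains no queries"))
    for path, label in ((cfg.gtf_path, "gtf"), (cfg.bed_path, "bed")):
        if path is not None and not os.access(path, os.R_OK):
            diags.append(Diagnostic("fatal", f"{label} file not readable: {path}"))

    def _dedup(keys: list[str], where: str) -> list[str]:
        seen: list[str] = []
        for k in keys:
            if k in seen:
                diags.append(
                    Diagnostic("warning", f"{where}: duplicate show-attribute '{k}' dropped")
                )
            else:
                seen.append(k)
        return seen

    cfg.global_show_attributes = _dedup(cfg.global_show_attributes, "global")
    for q in cfg.queries:
        q.show_attributes = _dedup(q.show_attributes, f"query {q.index}")
    return diags
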