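"""Readers and writers for the CLD exchange formats.

Edge-list dialect (CSV, UTF-8, header required)::

    group_id,cause,effect,polarity[,delay,cause_is_action,effect_is_action]

Polarity cells are exactly ``+`` or ``-``; the optional flag columns are
0/1.  The focal problem variable is run configuration, not a column: one
study has one focal problem, and keeping it out of the file keeps workshop
transcriptions minimal.

Graph exports (DOT and GraphML) and JSON reports emit nodes and edges in
lexicographic order, so identical inputs always produce identical bytes.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path
from typing import IO, Iterable, Mapping

import networkx as nx

from .model import (
    CldError,
    Edge,
    Factor,
    GroupModel,
    Polarity,
    merge_duplicate_edges,
    normalize_label,
)

__all__ = [
    "read_group_models",
    "read_synonym_map",
    "write_edge_list",
    "write_signed_graph",
    "write_report",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

REQUIRED_COLUMNS = ("group_id", "cause", "effect", "polarity")
OPTIONAL_COLUMNS = ("delay", "cause_is_action", "effect_is_action")


def _open_text(source: str | Path | IO[str]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.exists():
        return path.open(newline="", encoding="utf-8")
    if isinstance(source, str) and ("\n" in source or "," in source):
        return _io.StringIO(source)
    raise CldError(f"no such file: {source}")


def _parse_flag(value: str | None, column: str, row_num: int) -> bool:
    if value is None or value.strip() == "":
        return False
    if value.strip() in ("0", "1"):
        return value.strip() == "1"
    raise CldError(f"row {row_num}: invalid {column} {value!r}; expected 0 or 1")


def read_group_models(
    source: str | Path | IO[str], focal_label: str
) -> list[GroupModel]:
    """Parse an edge-list CSV into one GroupModel per group.

    ``source`` may be a path, an open text stream, or CSV text itself.
    Factors are inferred from edge endpoints (action flags OR-ed over
    rows); the focal factor — ``focal_label`` after default normalization —
    is added to every group when absent.  Duplicate rows within a group are
    collapsed, and models are returned sorted by group_id.  Labels are kept
    raw here; run :func:`cldkit.model.canonicalize_labels` afterwards.
    """
    focal = normalize_label(focal_label)
    if not focal:
        raise CldError("focal_label must be non-empty")
    stream = _open_text(source)
    try:
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            raise CldError("empty edge-list file")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CldError(f"missing required column(s): {', '.join(missing)}")

        rows_by_group: dict[str, list[Edge]] = {}
        flags: dict[str, dict[str, bool]] = {}
        n_rows = 0
        for row_num, row in enumerate(reader, start=2):
            n_rows += 1
            gid = (row["group_id"] or "").strip()
            if not gid:
                raise CldError(f"row {row_num}: empty group_id")
            cause = (row["cause"] or "").strip()
            effect = (row["effect"] or "").strip()
            if not cause or not effect:
                raise CldError(f"row {row_num}: empty cause or effect label")
            symbol = (row["polarity"] or "").strip()
            if symbol not in ("+", "-"):
                raise CldError(f"row {row_num}: invalid polarity {symbol!r}")
            if cause == effect:
                raise CldError(f"row {row_num}: self-edge {cause!r} -> {effect!r}")
            edge = Edge(
                cause=cause,
                effect=effect,
                polarity=Polarity.from_symbol(symbol),
                delay=_parse_flag(row.get("delay"), "delay", row_num),
                group_id=gid,
            )
            rows_by_group.setdefault(gid, []).append(edge)
            gflags = flags.setdefault(gid, {})
            if _parse_flag(row.get("cause_is_action"), "cause_is_action", row_num):
                gflags[cause] = True
            if _parse_flag(row.get("effect_is_action"), "effect_is_action", row_num):
                gflags[effect] = True
        if n_rows == 0:
            raise CldError("edge-list file contains a header but no rows")
    finally:
        if stream is not source:
            stream.close()

    models = []
    for gid in sorted(rows_by_group):
        edges = merge_duplicate_edges(rows_by_group[gid])
        labels = {e.cause for e in edges} | {e.effect for e in edges}
        factors = {
            label: Factor(id=label, is_action_idea=flags[gid].get(label, False))
            for label in sorted(labels)
        }
        if not any(normalize_label(label) == focal for label in labels):
            factors[focal] = Factor(id=focal)
            model_focal = focal
        else:
            # keep the raw spelling so canonicalization later unifies it
            model_focal = sorted(
                label for label in labels if normalize_label(label) == focal
            )[0]
        models.append(
            GroupModel(group_id=gid, factors=factors, edges=edges, focal=model_focal)
        )
    return models


def read_synonym_map(source: str | Path | IO[str]) -> dict[str, str]:
    """Parse a two-column ``raw,canonical`` CSV into a synonym mapping.

    Keys are normalized; duplicate identical rows collapse, but the same
    raw label mapped to two different canonicals is an error.
    """
    stream = _open_text(source)
    try:
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            return {}
        if [c.strip() for c in reader.fieldnames[:2]] != ["raw", "canonical"]:
            raise CldError(
                f"synonym map must have header 'raw,canonical', got {reader.fieldnames}"
            )
        mapping: dict[str, str] = {}
        for row in reader:
            raw = normalize_label(row["raw"] or "")
            canonical = normalize_label(row["canonical"] or "")
            if not raw or not canonical:
                raise CldError(f"synonym row with empty label: {row}")
            if raw in mapping and mapping[raw] != canonical:
                raise CldError(
                    f"conflicting canonical for {row['raw']!r}: "
                    f"{mapping[raw]!r} vs {canonical!r}"
                )
            mapping[raw] = canonical
        return mapping
    finally:
        if stream is not source:
            stream.close()


def write_edge_list(models: Iterable[GroupModel]) -> str:
    """Serialize group models back to the edge-list dialect (full columns)."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))
    for model in sorted(models, key=lambda m: m.group_id):
        actions = {f.id for f in model.factors.values() if f.is_action_idea}
        for edge in model.sorted_edges():
            writer.writerow(
                [
                    model.group_id,
                    edge.cause,
                    edge.effect,
                    edge.polarity.symbol,
                    int(edge.delay),
                    int(edge.cause in actions),
                    int(edge.effect in actions),
                ]
            )
    return buf.getvalue()


def _as_graph(graph) -> nx.MultiDiGraph:
    if isinstance(graph, nx.MultiDiGraph):
        return graph
    from .loops import build_graph  # local import to avoid a cycle

    if isinstance(graph, GroupModel):
        g = build_graph(graph.edges, nodes=graph.factors)
        for fid, factor in graph.factors.items():
            g.nodes[fid]["is_action_idea"] = factor.is_action_idea
        g.graph["focal"] = graph.focal
        return g
    raise CldError(f"cannot export object of type {type(graph).__name__}")


def write_signed_graph(graph, format: str = "dot", focal: str | None = None) -> str:
    """Render a signed digraph as DOT or GraphML text, byte-deterministic.

    DOT: negative edges dashed, the focal node double-circled, every edge
    annotated with its polarity (and support when present).  GraphML: edge
    keys "polarity" (string) and "support" (int, when present), node key
    "is_action_idea" (boolean).  Nodes and edges are emitted in
    lexicographic order.
    """
    g = _as_graph(graph)
    focal = focal or g.graph.get("focal")
    fmt = format.lower()
    if fmt == "dot":
        return _to_dot(g, focal)
    if fmt == "graphml":
        return _to_graphml(g)
    raise CldError(f"unknown graph format {format!r}; expected 'dot' or 'graphml'")


def _dot_id(label: str) -> str:
    return '"' + label.replace('"', '\\"') + '"'


def _to_dot(g: nx.MultiDiGraph, focal: str | None) -> str:
    lines = ["digraph cld {"]
    for node in sorted(g.nodes):
        attrs = []
        if node == focal:
            attrs.append("shape=doublecircle")
        if g.nodes[node].get("is_action_idea"):
            attrs.append("shape=box")
        lines.append(
            f"  {_dot_id(node)}" + (f" [{', '.join(attrs)}]" if attrs else "") + ";"
        )
    edges = sorted(
        (u, v, d.get("polarity", "+"), d.get("support"))
        for u, v, d in g.edges(data=True)
    )
    for u, v, polarity, support in edges:
        attrs = [f'polarity="{polarity}"']
        if polarity == "-":
            attrs.append("style=dashed")
        if support is not None:
            attrs.append(f"support={support}")
        lines.append(f"  {_dot_id(u)} -> {_dot_id(v)} [{', '.join(attrs)}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def _to_graphml(g: nx.MultiDiGraph) -> str:
    ordered = nx.MultiDiGraph()
    for node in sorted(g.nodes):
        ordered.add_node(node, is_action_idea=bool(g.nodes[node].get("is_action_idea", False)))
    for u, v, k, d in sorted(g.edges(keys=True, data=True)):
        attrs = {"polarity": d.get("polarity", "+")}
        if d.get("support") is not None:
            attrs["support"] = int(d["support"])
        ordered.add_edge(u, v, key=k, **attrs)
    return "\n".join(nx.generate_graphml(ordered, named_key_ids=True)) + "\n"


def write_report(report, schema_version: int = SCHEMA_VERSION) -> str:
    """Serialize a report object (dict or anything with ``to_report``) to
    deterministic JSON with a schema_version field."""
    if hasattr(report, "to_report"):
        report = report.to_report()
    if not isinstance(report, Mapping):
        raise CldError(f"cannot serialize report of type {type(report).__name__}")
    payload = {"schema_version": schema_version, **report}
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
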