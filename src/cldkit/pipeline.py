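"""End-to-end run orchestration: read → standardize → validate → aggregate
→ loop inventory → core extraction → indirect consensus → action influence.

All stage outputs land in one run directory together with a manifest
(configuration, input digests, package version) that suffices to reproduce
the run byte-for-byte; log lines carry timestamps but reports never do.
Everything is computed before anything is written, so a failing run leaves
no partial reports behind.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .actions import action_influence, action_report
from .aggregate import polarity_conflicts, summary_stats, union_models
from .core import core_report, extract_core, indirect_path_consensus
from .io import SCHEMA_VERSION, read_group_models, read_synonym_map, write_report, write_signed_graph
from .loops import build_graph, enumerate_simple_cycles, loop_inventory_report
from .model import CldError, canonicalize_labels, validate_group_model

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("cldkit")


@dataclass
class RunConfig:
    """Pipeline settings; YAML keys mirror the field names."""

    focal: str
    min_support: int = 2
    max_loop_len: int = 12
    max_loop_count: int = 100_000
    max_path_len: int = 4
    max_intermediates: int = 2
    seed: int = 0
    output_dir: Path = field(default_factory=lambda: Path("cld_run"))

    def __post_init__(self) -> None:
        if not self.focal or not str(self.focal).strip():
            raise CldError("focal must be non-empty")
        if self.min_support < 1:
            raise CldError("min_support must be >= 1")
        if self.max_loop_len < 2:
            raise CldError("max_loop_len must be >= 2")
        if self.max_path_len < 1:
            raise CldError("max_path_len must be >= 1")
        if self.max_intermediates < 1:
            raise CldError("max_intermediates must be >= 1")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise CldError(f"config file {path} must contain a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(data) - known
        if unknown:
            raise CldError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        """Manifest form: the run directory's own location is omitted so
        that identical analyses in different directories stay byte-equal."""
        data = asdict(self)
        del data["output_dir"]
        return data


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _csv_text(header: list[str], rows: list[list]) -> str:
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(header)
    writer.writerows(rows)
    return buf.getvalue()


def run_pipeline(
    edge_list: str | Path,
    synonym_map: str | Path | None,
    config: RunConfig,
) -> Path:
    """Execute the full analysis and write all reports under a run directory.

    Returns the run directory.  Raises :class:`CldError` on invalid inputs
    or configuration before any file is written.
    """
    log.info("reading edge list %s", edge_list)
    models = read_group_models(edge_list, focal_label=config.focal)
    synonyms = read_synonym_map(synonym_map) if synonym_map else {}
    models = canonicalize_labels(models, synonyms)

    log.info("validating %d group models", len(models))
    violations = {
        m.group_id: [f"{v.code}: {v.message}" for v in validate_group_model(m)]
        for m in models
    }
    flat = [f"[{gid}] {msg}" for gid, msgs in violations.items() for msg in msgs]
    if flat:
        raise CldError("invalid group models:\n" + "\n".join(flat))

    log.info("aggregating")
    stats = summary_stats(models)
    agg = union_models(models)
    focal = agg.focal
    if not any(focal in (e.cause, e.effect) for e in agg.edges.values()):
        raise CldError(f"focal factor {focal!r} has no causal links in the inputs")
    conflicts = polarity_conflicts(agg)

    log.info("enumerating per-group feedback loops")
    group_loops = {}
    for model in models:
        loops = enumerate_simple_cycles(
            build_graph(model.edges),
            max_len=config.max_loop_len,
            max_count=config.max_loop_count,
        )
        group_loops[model.group_id] = loop_inventory_report(loops)

    log.info("extracting core model (min_support=%d)", config.min_support)
    core = extract_core(agg, min_support=config.min_support, max_loop_len=config.max_loop_len)
    core_rep = core_report(core)

    log.info("computing indirect-path consensus")
    consensus = indirect_path_consensus(agg, models, max_intermediates=config.max_intermediates)

    log.info("tracing action-idea influence")
    influences = action_influence(agg, core, max_path_len=config.max_path_len)

    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log.info("writing reports to %s", out)

    (out / "per_group_stats.json").write_text(write_report(stats), encoding="utf-8")
    (out / "aggregate.json").write_text(write_report(agg), encoding="utf-8")
    (out / "support_table.csv").write_text(
        _csv_text(
            ["cause", "effect", "polarity", "support", "instance_count", "groups"],
            [
                [e.cause, e.effect, e.polarity.symbol, e.support, e.instance_count,
                 ";".join(sorted(e.supporting_groups))]
                for e in agg.sorted_edges()
            ],
        ),
        encoding="utf-8",
    )
    (out / "polarity_conflicts.csv").write_text(
        _csv_text(
            ["cause", "effect", "groups_plus", "groups_minus"],
            [[c, e, ";".join(gp), ";".join(gm)] for c, e, gp, gm in conflicts],
        ),
        encoding="utf-8",
    )
    (out / "loops.json").write_text(
        write_report({"per_group": group_loops}), encoding="utf-8"
    )
    (out / "core.csv").write_text(
        _csv_text(
            ["cause", "effect", "polarity", "support", "reason"],
            [
                [e.cause, e.effect, e.polarity.symbol, e.support,
                 core.reasons[e.key].value]
                for e in core.sorted_edges()
            ],
        ),
        encoding="utf-8",
    )
    core_graph = core.graph()
    for key, edge in core.edges.items():
        core_graph[edge.cause][edge.effect][edge.polarity.symbol]["support"] = edge.support
    (out / "core.dot").write_text(
        write_signed_graph(core_graph, "dot", focal=focal), encoding="utf-8"
    )
    (out / "core.graphml").write_text(
        write_signed_graph(core_graph, "graphml"), encoding="utf-8"
    )
    (out / "core_report.json").write_text(write_report(core_rep), encoding="utf-8")
    (out / "consensus.csv").write_text(
        _csv_text(
            ["cause", "effect", "polarity", "direct_support", "effective_support",
             "witness_paths"],
            [
                [r.cause, r.effect, r.polarity.symbol, r.direct_support,
                 r.effective_support,
                 ";".join(f"{gid}:{'->'.join(path)}" for gid, path in r.indirect_groups)]
                for r in consensus
            ],
        ),
        encoding="utf-8",
    )
    (out / "actions.csv").write_text(
        _csv_text(
            ["action", "core_node", "path", "signs", "net_polarity"],
            [
                [row["action"], row["core_node"], row["path"], row["signs"],
                 row["net_polarity"]]
                for influence in influences
                for row in (p.to_row() for p in influence.pathways)
            ],
        ),
        encoding="utf-8",
    )
    (out / "action_totals.json").write_text(
        write_report(action_report(influences)), encoding="utf-8"
    )

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "cldkit_version": __version__,
        "config": config.to_dict(),
        "inputs": {
            "edge_list_sha256": _sha256(edge_list),
            "synonym_map_sha256": _sha256(synonym_map) if synonym_map else None,
        },
        "n_groups": len(models),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    log.info("run complete")
    return out
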