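"""Consensus core-model extraction and indirect-path consensus.

The core model keeps the union edges that (a) at least ``min_support``
groups mentioned, and that (b) sit on a feedback loop or on a directed
causal path to or from the focal problem variable — evaluated *within the
surviving edge set* and iterated to a fixed point, so structure that only
qualified through since-removed edges is pruned too.  Nodes left without
edges drop out, which removes exogenous stubs.

Indirect-path consensus asks, for each union edge, whether groups lacking
the direct edge nonetheless drew a short directed path from its cause to
its effect with the same net sign; such witness paths raise the edge's
effective support.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import networkx as nx

from .aggregate import AggregateEdge, AggregateModel
from .loops import build_graph, enumerate_simple_cycles, feedback_edges, loop_inventory_report
from .model import CldError, GroupModel, Polarity

__all__ = [
    "EdgeReason",
    "CoreModel",
    "ConsensusRecord",
    "extract_core",
    "causal_connectivity",
    "indirect_path_consensus",
    "core_report",
]


class EdgeReason(Enum):
    """Why an edge survived core extraction."""

    FEEDBACK = "feedback"
    FOCAL_CONNECTED = "focal_connected"
    BOTH = "both"


@dataclass
class CoreModel:
    """The consensus subgraph with per-edge support and qualifying reason."""

    nodes: set[str]
    edges: dict[tuple[str, str, str], AggregateEdge]
    reasons: dict[tuple[str, str, str], EdgeReason]
    focal: str
    min_support: int
    max_loop_len: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> list[AggregateEdge]:
        return [self.edges[k] for k in sorted(self.edges)]

    def graph(self) -> nx.MultiDiGraph:
        return build_graph(self.edges.values(), nodes=self.nodes)


def causal_connectivity(
    graph: nx.MultiDiGraph, focal: str
) -> set[tuple[str, str, str]]:
    """Edges on some directed path ending at, or starting from, the focal node.

    Edge u->v qualifies iff v reaches focal (or v == focal) — an ancestor
    path — or focal reaches u (or u == focal) — a descendant path.  Both
    directions count because the focal problem is narrated as both effect
    and cause.  Returns (cause, effect, polarity symbol) triples.
    """
    if focal not in graph:
        return set()
    collapsed = nx.DiGraph(graph)
    ancestors = nx.ancestors(collapsed, focal) | {focal}
    descendants = nx.descendants(collapsed, focal) | {focal}
    return {
        (u, v, d["polarity"])
        for u, v, d in graph.edges(data=True)
        if v in ancestors or u in descendants
    }


def extract_core(
    agg: AggregateModel, min_support: int = 2, max_loop_len: int = 12
) -> CoreModel:
    """Extract the consensus core model from the union of group CLDs.

    Fixed-point filter: (1) keep edges with support >= min_support; (2)
    within the kept set, keep an edge iff it lies on a simple cycle or on a
    directed path to/from the focal variable; (3) repeat (2) until stable —
    removals can break previously qualifying cycles and paths ("incomplete"
    feedback structure is excluded); (4) drop edge-less nodes.

    ``max_loop_len`` is recorded as provenance and bounds the loop
    inventory of :func:`core_report`; cycle *membership* during filtering
    is exact (SCC-based) and unbounded.
    """
    if min_support < 1:
        raise CldError(f"min_support must be >= 1, got {min_support}")
    if agg.focal not in agg.factors:
        raise CldError(f"focal {agg.focal!r} not among aggregate factors")

    kept = {k: e for k, e in agg.edges.items() if e.support >= min_support}
    while True:
        graph = build_graph(kept.values())
        fb = feedback_edges(graph)
        conn = causal_connectivity(graph, agg.focal)
        surviving = {k: e for k, e in kept.items() if k in fb or k in conn}
        if len(surviving) == len(kept):
            break
        kept = surviving

    reasons = {
        k: (
            EdgeReason.BOTH
            if (k in fb and k in conn)
            else EdgeReason.FEEDBACK
            if k in fb
            else EdgeReason.FOCAL_CONNECTED
        )
        for k in kept
    }
    nodes = {e.cause for e in kept.values()} | {e.effect for e in kept.values()}
    return CoreModel(
        nodes=nodes,
        edges=kept,
        reasons=reasons,
        focal=agg.focal,
        min_support=min_support,
        max_loop_len=max_loop_len,
    )


@dataclass(frozen=True)
class ConsensusRecord:
    """Direct plus indirect (witness-path) support for one union edge."""

    cause: str
    effect: str
    polarity: Polarity
    direct_groups: tuple[str, ...]
    indirect_groups: tuple[tuple[str, tuple[str, ...]], ...]  # (group, node path)
    effective_support: int

    @property
    def direct_support(self) -> int:
        return len(self.direct_groups)

    @property
    def gain(self) -> int:
        return self.effective_support - self.direct_support


def _witness_path(
    graph: nx.MultiDiGraph,
    cause: str,
    effect: str,
    target: Polarity,
    max_intermediates: int,
) -> tuple[str, ...] | None:
    """Shortest-first DFS for a simple path cause->..->effect with >= 1
    intermediate, <= max_intermediates intermediates, and net sign == target."""
    if cause not in graph or effect not in graph:
        return None

    def dfs(node: str, path: tuple[str, ...], sign: Polarity) -> tuple[str, ...] | None:
        if len(path) - 1 > max_intermediates:
            return None
        for succ in sorted(graph.successors(node)):
            signs = {d["polarity"] for d in graph[node][succ].values()}
            for symbol in sorted(signs):
                hop = sign * Polarity.from_symbol(symbol)
                if succ == effect:
                    if len(path) >= 2 and hop is target:
                        return path + (effect,)
                elif succ not in path:
                    found = dfs(succ, path + (succ,), hop)
                    if found is not None:
                        return found
        return None

    return dfs(cause, (cause,), Polarity.POSITIVE)


def indirect_path_consensus(
    agg: AggregateModel,
    models: Iterable[GroupModel],
    max_intermediates: int = 2,
) -> list[ConsensusRecord]:
    """Effective support of each union edge once witness paths are counted.

    A group that did not draw edge (cause, effect, polarity) still endorses
    it indirectly when its own CLD contains a simple directed path
    cause -> ... -> effect through at most ``max_intermediates`` intervening
    nodes whose sign product equals the edge's polarity.  One witness path
    per group is recorded.  Records are sorted by consensus gain
    (effective - direct support) descending, then lexicographically.
    """
    models = {m.group_id: m for m in models}
    missing = [g for g in agg.group_ids if g not in models]
    if missing:
        raise CldError(f"aggregate references groups absent from models: {missing}")
    graphs = {gid: build_graph(m.edges) for gid, m in models.items()}

    records = []
    for edge in agg.sorted_edges():
        direct = tuple(sorted(edge.supporting_groups))
        indirect = []
        for gid in agg.group_ids:
            if gid in edge.supporting_groups:
                continue
            path = _witness_path(
                graphs[gid], edge.cause, edge.effect, edge.polarity, max_intermediates
            )
            if path is not None:
                indirect.append((gid, path))
        records.append(
            ConsensusRecord(
                cause=edge.cause,
                effect=edge.effect,
                polarity=edge.polarity,
                direct_groups=direct,
                indirect_groups=tuple(indirect),
                effective_support=len(direct) + len(indirect),
            )
        )
    records.sort(key=lambda r: (-r.gain, r.cause, r.effect, r.polarity.symbol))
    return records


def core_report(core: CoreModel) -> dict:
    """Core-model summary: size, loop inventory, reasons, support histogram."""
    loops = enumerate_simple_cycles(core.graph(), max_len=core.max_loop_len)
    histogram: dict[int, int] = {}
    for edge in core.edges.values():
        histogram[edge.support] = histogram.get(edge.support, 0) + 1
    return {
        "n_nodes": core.n_nodes,
        "n_edges": core.n_edges,
        "focal": core.focal,
        "min_support": core.min_support,
        "max_loop_len": core.max_loop_len,
        "reason_counts": {
            reason.value: sum(1 for r in core.reasons.values() if r is reason)
            for reason in EdgeReason
        },
        "support_histogram": {str(k): histogram[k] for k in sorted(histogram)},
        "loop_inventory": loop_inventory_report(loops),
    }
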