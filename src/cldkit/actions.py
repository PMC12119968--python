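"""Leverage analysis of action ideas against the consensus core model.

Action ideas are participant-proposed interventions represented as nodes;
their leverage is read off the signed directed paths from each action node
to the nodes of the core model.  Paths traverse the full aggregate (union)
graph, not only core edges — an action influences the system through any
elicited linkage.  Because the published tally does not say whether it
counts (action, core node) pairs or distinct pathways, both totals are
always reported side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .aggregate import AggregateModel
from .core import CoreModel
from .loops import build_graph
from .model import CldError, Polarity

__all__ = [
    "Pathway",
    "ActionInfluence",
    "find_action_nodes",
    "path_net_polarity",
    "action_influence",
    "action_report",
]

DEFAULT_MAX_PATH_LEN = 4


@dataclass(frozen=True)
class Pathway:
    """One simple signed path from an action node to a core node."""

    nodes: tuple[str, ...]
    polarities: tuple[Polarity, ...]

    @property
    def net_polarity(self) -> Polarity:
        return Polarity.product(self.polarities)

    @property
    def target(self) -> str:
        return self.nodes[-1]

    def to_row(self) -> dict:
        return {
            "action": self.nodes[0],
            "core_node": self.target,
            "path": " -> ".join(self.nodes),
            "signs": "".join(p.symbol for p in self.polarities),
            "net_polarity": self.net_polarity.symbol,
        }


@dataclass
class ActionInfluence:
    """All influence pathways of one action idea on the core model."""

    action: str
    reached_core_nodes: tuple[str, ...]
    pathways: tuple[Pathway, ...]

    @property
    def n_pairs(self) -> int:
        return len(self.reached_core_nodes)

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)


def find_action_nodes(agg: AggregateModel) -> list[str]:
    """Factors flagged as action ideas, sorted."""
    return agg.action_ideas()


def path_net_polarity(edges: Sequence) -> Polarity:
    """Sign product along a connected directed walk of signed edges.

    Accepts Edge-like objects or (cause, effect, Polarity) tuples; raises
    if consecutive edges do not chain cause-to-effect.
    """
    triples = [
        (e[0], e[1], e[2]) if isinstance(e, tuple) else (e.cause, e.effect, e.polarity)
        for e in edges
    ]
    for (_, effect, _), (cause, _, _) in zip(triples, triples[1:]):
        if effect != cause:
            raise CldError(
                f"edges do not form a contiguous walk: {effect!r} != {cause!r}"
            )
    return Polarity.product(p for _, _, p in triples)


def action_influence(
    agg: AggregateModel,
    core: CoreModel,
    max_path_len: int = DEFAULT_MAX_PATH_LEN,
) -> list[ActionInfluence]:
    """Enumerate bounded simple paths from every action node into the core.

    For each action idea, every simple directed path of at most
    ``max_path_len`` edges through the aggregate graph that ends at a core
    node is a pathway; parallel edges of different sign yield distinct
    pathways.  Results sorted by action id; pathways sorted by
    (target, nodes, signs).
    """
    if max_path_len < 1:
        raise CldError(f"max_path_len must be >= 1, got {max_path_len}")
    graph = build_graph(agg.edges.values())
    core_nodes = set(core.nodes)
    influences = []
    for action in find_action_nodes(agg):
        pathways: list[Pathway] = []
        if action in graph:
            _collect(graph, action, core_nodes, max_path_len, (action,), (), pathways)
        pathways.sort(key=lambda p: (p.target, p.nodes, tuple(s.symbol for s in p.polarities)))
        reached = tuple(sorted({p.target for p in pathways}))
        influences.append(
            ActionInfluence(action=action, reached_core_nodes=reached, pathways=tuple(pathways))
        )
    return influences


def _collect(
    graph,
    node: str,
    core_nodes: set[str],
    budget: int,
    path: tuple[str, ...],
    signs: tuple[Polarity, ...],
    out: list[Pathway],
) -> None:
    if budget == 0:
        return
    for succ in sorted(graph.successors(node)):
        if succ in path:
            continue
        for symbol in sorted({d["polarity"] for d in graph[node][succ].values()}):
            new_path = path + (succ,)
            new_signs = signs + (Polarity.from_symbol(symbol),)
            if succ in core_nodes:
                out.append(Pathway(nodes=new_path, polarities=new_signs))
            _collect(graph, succ, core_nodes, budget - 1, new_path, new_signs, out)


def action_report(influences: Iterable[ActionInfluence]) -> dict:
    """JSON-ready totals; pair and pathway counts are both reported because
    either is a defensible reading of "ways an action affects the core"."""
    influences = list(influences)
    return {
        "n_action_ideas": len(influences),
        "n_actions_with_influence": sum(1 for a in influences if a.n_pathways > 0),
        "total_action_core_pairs": sum(a.n_pairs for a in influences),
        "total_pathways": sum(a.n_pathways for a in influences),
        "per_action": [
            {
                "action": a.action,
                "n_core_nodes_reached": a.n_pairs,
                "n_pathways": a.n_pathways,
                "reached_core_nodes": list(a.reached_core_nodes),
            }
            for a in influences
        ],
    }
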