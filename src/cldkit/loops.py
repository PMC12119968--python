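"""Feedback-loop enumeration and polarity classification for signed digraphs.

A feedback loop is a simple directed cycle.  Its character follows the
standard system-dynamics sign-product rule: a loop with an even number of
negative links is *reinforcing* (amplifies change), odd is *balancing*
(counteracts change).  Because the same ordered node pair may carry both a
``+`` and a ``-`` edge, one node cycle can yield several distinct loops,
one per combination of parallel-edge signs.

Graphs are :class:`networkx.MultiDiGraph` objects whose parallel edges are
keyed by polarity symbol and carry a ``polarity`` attribute ("+"/"-");
:func:`build_graph` constructs them from any edge collection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import networkx as nx

from .model import CldError, Polarity

__all__ = [
    "LoopClass",
    "Loop",
    "LoopCapExceeded",
    "build_graph",
    "enumerate_simple_cycles",
    "classify_loop",
    "exogenous_nodes",
    "feedback_edges",
    "loop_inventory_report",
]

#: Participant-built CLDs are small; these caps guard against blowup on
#: dense synthetic graphs while making truncation explicit, never silent.
DEFAULT_MAX_LOOP_LEN = 12
DEFAULT_MAX_LOOP_COUNT = 100_000


class LoopClass(Enum):
    REINFORCING = "reinforcing"
    BALANCING = "balancing"


@dataclass(frozen=True)
class Loop:
    """A simple directed cycle in canonical rotation.

    ``nodes`` starts at the lexicographically smallest node of the cycle;
    ``polarities`` lists the sign of each hop in traversal order, the last
    entry closing the cycle back to ``nodes[0]``.
    """

    nodes: tuple[str, ...]
    polarities: tuple[Polarity, ...]

    @property
    def n_negative(self) -> int:
        return sum(1 for p in self.polarities if p is Polarity.NEGATIVE)

    @property
    def classification(self) -> LoopClass:
        return LoopClass.REINFORCING if self.n_negative % 2 == 0 else LoopClass.BALANCING

    @property
    def edges(self) -> tuple[tuple[str, str, Polarity], ...]:
        """Cycle edges in traversal order, including the closing hop."""
        cycle = self.nodes + (self.nodes[0],)
        return tuple(
            (cycle[i], cycle[i + 1], self.polarities[i]) for i in range(len(self.nodes))
        )

    def sort_key(self) -> tuple:
        return (len(self.nodes), self.nodes, tuple(p.symbol for p in self.polarities))

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "polarities": [p.symbol for p in self.polarities],
            "n_negative": self.n_negative,
            "classification": self.classification.value,
        }


class LoopCapExceeded(CldError):
    """More cycles exist than ``max_count``; carries the partial inventory."""

    def __init__(self, max_count: int, partial: list[Loop]):
        super().__init__(
            f"cycle enumeration exceeded the cap of {max_count}; "
            f"{len(partial)} loops collected before stopping"
        )
        self.max_count = max_count
        self.partial = partial


def build_graph(edges: Iterable, nodes: Iterable[str] = ()) -> nx.MultiDiGraph:
    """Build a polarity-keyed MultiDiGraph from Edge/AggregateEdge objects
    or (cause, effect, Polarity) tuples."""
    g = nx.MultiDiGraph()
    for node in nodes:
        g.add_node(node)
    for e in edges:
        if isinstance(e, tuple):
            cause, effect, polarity = e[0], e[1], e[2]
        else:
            cause, effect, polarity = e.cause, e.effect, e.polarity
        g.add_edge(cause, effect, key=polarity.symbol, polarity=polarity.symbol)
    return g


def _canonical_rotation(cycle: list[str]) -> list[str]:
    i = cycle.index(min(cycle))
    return cycle[i:] + cycle[:i]


def _arc_polarities(graph: nx.MultiDiGraph, u: str, v: str) -> list[Polarity]:
    return sorted(
        (Polarity.from_symbol(d["polarity"]) for d in graph[u][v].values()),
        key=lambda p: p.symbol,
    )


def enumerate_simple_cycles(
    graph: nx.MultiDiGraph,
    max_len: int = DEFAULT_MAX_LOOP_LEN,
    max_count: int = DEFAULT_MAX_LOOP_COUNT,
) -> list[Loop]:
    """Every simple directed cycle of length <= max_len, as canonical Loops.

    Node cycles come from networkx's elementary-cycle search; each cycle is
    then expanded over the polarity combinations of its arcs, so an arc
    carrying both signs contributes one loop per sign.  The result is sorted
    by (length, node sequence, sign sequence).  If more than ``max_count``
    loops exist, :class:`LoopCapExceeded` is raised carrying the loops found
    so far — results are never silently truncated.
    """
    if max_len < 2:
        raise CldError(f"max_len must be >= 2, got {max_len}")
    if max_count < 1:
        raise CldError(f"max_count must be >= 1, got {max_count}")
    collapsed = nx.DiGraph(graph)
    loops: list[Loop] = []
    for cycle in nx.simple_cycles(collapsed, length_bound=max_len):
        nodes = _canonical_rotation(list(cycle))
        arcs = list(zip(nodes, nodes[1:] + nodes[:1]))
        sign_choices = [_arc_polarities(graph, u, v) for u, v in arcs]
        for signs in itertools.product(*sign_choices):
            loops.append(Loop(nodes=tuple(nodes), polarities=tuple(signs)))
            if len(loops) > max_count:
                loops.sort(key=Loop.sort_key)
                raise LoopCapExceeded(max_count, loops)
    loops.sort(key=Loop.sort_key)
    return loops


def classify_loop(loop: Loop) -> LoopClass:
    """Reinforcing iff the number of negative links is even (sign product +)."""
    return loop.classification


def exogenous_nodes(graph: nx.MultiDiGraph) -> list[str]:
    """Nodes with no incoming edge — factors the system does not cause.

    Returned sorted for determinism.
    """
    return sorted(n for n in graph.nodes if graph.in_degree(n) == 0)


def feedback_edges(graph: nx.MultiDiGraph) -> set[tuple[str, str, str]]:
    """Edges lying on at least one simple directed cycle.

    With self-edges excluded, an edge u->v is on a cycle iff u and v share a
    strongly connected component of >= 2 nodes; this equals the edge union
    of full cycle enumeration but costs only one SCC pass.  Returns
    (cause, effect, polarity symbol) triples — both parallel signs qualify
    when the node pair is cyclic.
    """
    collapsed = nx.DiGraph(graph)
    comp_of: dict[str, int] = {}
    for i, comp in enumerate(nx.strongly_connected_components(collapsed)):
        if len(comp) >= 2:
            for node in comp:
                comp_of[node] = i
    return {
        (u, v, d["polarity"])
        for u, v, d in graph.edges(data=True)
        if u in comp_of and comp_of[u] == comp_of.get(v, -1)
    }


def loop_inventory_report(loops: list[Loop]) -> dict:
    """JSON-ready loop inventory with counts by class."""
    return {
        "n_loops": len(loops),
        "n_reinforcing": sum(1 for l in loops if l.classification is LoopClass.REINFORCING),
        "n_balancing": sum(1 for l in loops if l.classification is LoopClass.BALANCING),
        "loops": [l.to_dict() for l in loops],
    }
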