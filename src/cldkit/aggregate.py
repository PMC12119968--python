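"""Union aggregation of group CLDs with per-edge group support.

All workshop groups are taken to describe aspects of one underlying system,
so their models are merged as the union set of edges.  Edge identity is the
(cause, effect, polarity) triple — the same factor pair may carry both
signs, and such sign disagreements are surfaced by
:func:`polarity_conflicts` rather than resolved.  Each union edge records
which groups mentioned it; that *support* count drives the downstream
consensus core extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .model import CldError, Factor, GroupModel, Polarity

__all__ = [
    "AggregateEdge",
    "AggregateModel",
    "PerGroupStats",
    "union_models",
    "summary_stats",
    "polarity_conflicts",
]


@dataclass(frozen=True)
class AggregateEdge:
    """One (cause, effect, polarity) edge of the union model.

    ``instance_count`` tallies edge instances across groups; because group
    models are deduplicated on read, it equals the number of supporting
    groups, but it is kept as a separate field for audit.
    """

    cause: str
    effect: str
    polarity: Polarity
    supporting_groups: frozenset[str]
    instance_count: int
    delay: bool = False

    @property
    def support(self) -> int:
        return len(self.supporting_groups)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cause, self.effect, self.polarity.symbol)


@dataclass
class AggregateModel:
    """Union of all group models: merged factors, supported edges, focal."""

    group_ids: list[str]
    factors: dict[str, Factor]
    edges: dict[tuple[str, str, str], AggregateEdge]
    focal: str

    def sorted_edges(self) -> list[AggregateEdge]:
        return [self.edges[k] for k in sorted(self.edges)]

    @property
    def total_edge_instances(self) -> int:
        return sum(e.instance_count for e in self.edges.values())

    @property
    def n_unique_combinations(self) -> int:
        return len(self.edges)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def action_ideas(self) -> list[str]:
        return sorted(f.id for f in self.factors.values() if f.is_action_idea)

    @property
    def n_action_ideas(self) -> int:
        return len(self.action_ideas())

    @property
    def n_edges_touching_action_ideas(self) -> int:
        """Edges with at least one action-flagged endpoint (weakest reading
        of "connected to action ideas")."""
        actions = set(self.action_ideas())
        return sum(
            1 for e in self.edges.values() if e.cause in actions or e.effect in actions
        )

    @property
    def n_edges_with_action_cause(self) -> int:
        """Stricter companion count: edges whose cause is an action idea."""
        actions = set(self.action_ideas())
        return sum(1 for e in self.edges.values() if e.cause in actions)

    def to_report(self) -> dict:
        return {
            "n_groups": len(self.group_ids),
            "total_edge_instances": self.total_edge_instances,
            "n_unique_combinations": self.n_unique_combinations,
            "n_factors": self.n_factors,
            "n_action_ideas": self.n_action_ideas,
            "n_edges_touching_action_ideas": self.n_edges_touching_action_ideas,
            "n_edges_with_action_cause": self.n_edges_with_action_cause,
            "focal": self.focal,
        }


def union_models(models: Iterable[GroupModel]) -> AggregateModel:
    """Merge group models into the union edge set with per-edge support.

    Requires at least one model, distinct group ids, and a shared focal id.
    Factor action flags are OR-ed across groups; raw labels are unioned.
    """
    models = list(models)
    if not models:
        raise CldError("union_models requires at least one group model")
    group_ids = [m.group_id for m in models]
    if len(set(group_ids)) != len(group_ids):
        raise CldError(f"duplicate group_ids: {sorted(group_ids)}")
    focals = {m.focal for m in models}
    if len(focals) != 1:
        raise CldError(f"models disagree on the focal variable: {sorted(focals)}")

    factors: dict[str, Factor] = {}
    for model in models:
        for factor in model.factors.values():
            prior = factors.get(factor.id)
            if prior is None:
                factors[factor.id] = Factor(
                    id=factor.id,
                    raw_labels=factor.raw_labels,
                    theme=factor.theme,
                    is_action_idea=factor.is_action_idea,
                )
            else:
                factors[factor.id] = Factor(
                    id=factor.id,
                    raw_labels=prior.raw_labels | factor.raw_labels,
                    theme=prior.theme or factor.theme,
                    is_action_idea=prior.is_action_idea or factor.is_action_idea,
                )

    support: dict[tuple[str, str, str], set[str]] = {}
    instances: dict[tuple[str, str, str], int] = {}
    delays: dict[tuple[str, str, str], bool] = {}
    for model in models:
        for edge in model.edges:
            support.setdefault(edge.key, set()).add(model.group_id)
            instances[edge.key] = instances.get(edge.key, 0) + 1
            delays[edge.key] = delays.get(edge.key, False) or edge.delay

    edges = {
        key: AggregateEdge(
            cause=key[0],
            effect=key[1],
            polarity=Polarity.from_symbol(key[2]),
            supporting_groups=frozenset(groups),
            instance_count=instances[key],
            delay=delays[key],
        )
        for key, groups in support.items()
    }
    return AggregateModel(
        group_ids=sorted(group_ids),
        factors=factors,
        edges=edges,
        focal=models[0].focal,
    )


@dataclass
class PerGroupStats:
    """Per-group factor/edge/action-idea counts with mean and range rows."""

    rows: list[dict] = field(default_factory=list)

    _COLUMNS = ("n_factors", "n_edges", "n_action_ideas")

    def column(self, name: str) -> list[int]:
        return [r[name] for r in self.rows]

    def summary(self) -> dict:
        out: dict = {}
        for col in self._COLUMNS:
            values = self.column(col)
            out[col] = {
                "mean": round(sum(values) / len(values), 1),
                "min": min(values),
                "max": max(values),
            }
        return out

    def to_report(self) -> dict:
        return {"groups": self.rows, "summary": self.summary()}


def summary_stats(models: Iterable[GroupModel]) -> PerGroupStats:
    """Exact per-group counts plus mean (1 decimal) and min–max range."""
    models = list(models)
    if not models:
        raise CldError("summary_stats requires at least one group model")
    rows = [
        {
            "group_id": m.group_id,
            "n_factors": len(m.factors),
            "n_edges": len(m.edges),
            "n_action_ideas": m.n_action_ideas(),
        }
        for m in sorted(models, key=lambda m: m.group_id)
    ]
    return PerGroupStats(rows=rows)


def polarity_conflicts(
    agg: AggregateModel,
) -> list[tuple[str, str, tuple[str, ...], tuple[str, ...]]]:
    """Ordered pairs carrying both signs: (cause, effect, +groups, -groups).

    Sorted lexicographically; empty when no group-level sign disagreement
    exists.
    """
    by_pair: dict[tuple[str, str], dict[str, AggregateEdge]] = {}
    for edge in agg.edges.values():
        by_pair.setdefault((edge.cause, edge.effect), {})[edge.polarity.symbol] = edge
    conflicts = []
    for (cause, effect), signs in sorted(by_pair.items()):
        if "+" in signs and "-" in signs:
            conflicts.append(
                (
                    cause,
                    effect,
                    tuple(sorted(signs["+"].supporting_groups)),
                    tuple(sorted(signs["-"].supporting_groups)),
                )
            )
    return conflicts
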