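"""Domain types for signed causal loop diagrams (CLDs).

A CLD is a signed directed graph: nodes are *factors* elicited in a group
model-building workshop, edges assert causal influence with a polarity.
A ``+`` edge means cause and effect move in the same direction, a ``-``
edge means they move in opposite directions.  Each workshop group produces
one :class:`GroupModel` built around a single focal problem variable.

Factor labels arrive as free text; :func:`canonicalize_labels` standardizes
them (optionally through a synonym map) so that the same concept voiced by
different groups becomes one factor across all models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "Polarity",
    "Factor",
    "Edge",
    "GroupModel",
    "Violation",
    "CldError",
    "normalize_label",
    "resolve_synonyms",
    "canonicalize_labels",
    "validate_group_model",
    "merge_duplicate_edges",
]


class CldError(ValueError):
    """Raised for structurally invalid CLD inputs or operations."""


class Polarity(Enum):
    """Sign of a causal edge: same-direction (+) or opposite-direction (-)."""

    POSITIVE = "+"
    NEGATIVE = "-"

    @classmethod
    def from_symbol(cls, symbol: str) -> "Polarity":
        try:
            return cls(symbol)
        except ValueError:
            raise CldError(f"invalid polarity {symbol!r}; expected '+' or '-'") from None

    @property
    def symbol(self) -> str:
        return self.value

    def __mul__(self, other: "Polarity") -> "Polarity":
        if not isinstance(other, Polarity):
            return NotImplemented
        return Polarity.POSITIVE if self is other else Polarity.NEGATIVE

    @staticmethod
    def product(polarities: Iterable["Polarity"]) -> "Polarity":
        """Sign product of a sequence; POSITIVE iff negatives are even."""
        n_neg = sum(1 for p in polarities if p is Polarity.NEGATIVE)
        return Polarity.POSITIVE if n_neg % 2 == 0 else Polarity.NEGATIVE

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Default label standardization: case-fold, trim, collapse internal
    whitespace to single underscores."""
    return _WS.sub("_", label.strip().casefold())


@dataclass
class Factor:
    """A factor (node): canonical id plus the raw labels it was elicited as."""

    id: str
    raw_labels: frozenset[str] = field(default_factory=frozenset)
    theme: str | None = None
    is_action_idea: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise CldError("factor id must be non-empty")
        if not self.raw_labels:
            self.raw_labels = frozenset({self.id})


@dataclass(frozen=True)
class Edge:
    """A signed causal edge.  Identity is (cause, effect, polarity); the delay
    flag is annotation only and never participates in identity."""

    cause: str
    effect: str
    polarity: Polarity
    delay: bool = False
    group_id: str = ""

    def __post_init__(self) -> None:
        if self.cause == self.effect:
            raise CldError(f"self-edge not allowed: {self.cause!r} -> {self.effect!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        """The (cause, effect, polarity symbol) identity triple."""
        return (self.cause, self.effect, self.polarity.symbol)


@dataclass
class GroupModel:
    """One workshop group's CLD: factors, signed edges, focal problem variable."""

    group_id: str
    factors: dict[str, Factor]
    edges: set[Edge]
    focal: str

    def factor_ids(self) -> list[str]:
        return sorted(self.factors)

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges, key=lambda e: e.key)

    def n_action_ideas(self) -> int:
        return sum(1 for f in self.factors.values() if f.is_action_idea)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_group_model`."""

    code: str
    message: str


def merge_duplicate_edges(edges: Iterable[Edge]) -> set[Edge]:
    """Collapse edges sharing (cause, effect, polarity); delay flags are OR-ed.

    All edges must belong to one group.  Order-independent.
    """
    merged: dict[tuple[str, str, str], Edge] = {}
    group_ids: set[str] = set()
    for edge in edges:
        group_ids.add(edge.group_id)
        if len(group_ids) > 1:
            raise CldError(f"mixed group_ids in edge list: {sorted(group_ids)}")
        prior = merged.get(edge.key)
        if prior is None:
            merged[edge.key] = edge
        elif edge.delay and not prior.delay:
            merged[edge.key] = replace(prior, delay=True)
    return set(merged.values())


def validate_group_model(model: GroupModel) -> list[Violation]:
    """Check all GroupModel invariants; returns violations, never raises.

    An empty report means the model is valid.  The input is not mutated.
    """
    violations: list[Violation] = []
    if model.focal not in model.factors:
        violations.append(
            Violation("focal-missing", f"focal {model.focal!r} not in factor set")
        )
    for fid, factor in sorted(model.factors.items()):
        if fid != factor.id:
            violations.append(
                Violation("factor-id-mismatch", f"key {fid!r} != factor id {factor.id!r}")
            )
        if not factor.raw_labels:
            violations.append(
                Violation("factor-raw-labels-empty", f"factor {fid!r} has no raw labels")
            )
    seen_keys: set[tuple[str, str, str]] = set()
    for edge in sorted(model.edges, key=lambda e: e.key):
        for endpoint in (edge.cause, edge.effect):
            if endpoint not in model.factors:
                violations.append(
                    Violation(
                        "edge-endpoint-missing",
                        f"edge {edge.cause!r}->{edge.effect!r} ({edge.polarity.symbol}) "
                        f"endpoint {endpoint!r} not in factor set",
                    )
                )
        if edge.group_id != model.group_id:
            violations.append(
                Violation(
                    "edge-group-mismatch",
                    f"edge {edge.cause!r}->{edge.effect!r} carries group "
                    f"{edge.group_id!r}, model is {model.group_id!r}",
                )
            )
        if edge.key in seen_keys:
            violations.append(
                Violation("duplicate-edge", f"duplicate edge identity {edge.key!r}")
            )
        seen_keys.add(edge.key)
    return violations


def resolve_synonyms(synonym_map: Mapping[str, str]) -> dict[str, str]:
    """Normalize and transitively resolve a raw→canonical synonym map.

    Keys and values are normalized with :func:`normalize_label`; chains
    (a→b, b→c) are followed to their fixed point so canonicalization is
    idempotent.  Cyclic chains raise :class:`CldError`.
    """
    normalized: dict[str, str] = {}
    for raw, canonical in synonym_map.items():
        key = normalize_label(raw)
        value = normalize_label(canonical)
        if not value:
            raise CldError(f"empty canonical label for raw {raw!r}")
        if key in normalized and normalized[key] != value:
            raise CldError(
                f"conflicting canonical for {raw!r}: "
                f"{normalized[key]!r} vs {value!r}"
            )
        normalized[key] = value
    resolved: dict[str, str] = {}
    for key in normalized:
        target = key
        seen = {key}
        while target in normalized and normalized[target] != target:
            target = normalized[target]
            if target in seen:
                raise CldError(f"cyclic synonym chain involving {key!r}")
            seen.add(target)
        resolved[key] = target
    return resolved


def _canon(label: str, resolved: Mapping[str, str]) -> str:
    n = normalize_label(label)
    return resolved.get(n, n)


def canonicalize_labels(
    models: Iterable[GroupModel], synonym_map: Mapping[str, str] | None = None
) -> list[GroupModel]:
    """Standardize factor labels across group models.

    Every factor id becomes the mapped canonical label when the synonym map
    has an entry for its normalized form, otherwise the normalized form
    itself.  Factors that collapse onto one canonical id are merged:
    raw_labels are unioned, action flags OR-ed, the first non-empty theme
    kept.  Edges are rewritten to canonical ids; exact duplicate edges
    produced by merging are collapsed (delay OR-ed).

    Raises :class:`CldError` if a mapping would turn an edge into a
    self-edge, naming the edge and the two raw labels merged.
    """
    resolved = resolve_synonyms(synonym_map or {})
    out: list[GroupModel] = []
    for model in models:
        factors: dict[str, Factor] = {}
        for factor in model.factors.values():
            cid = _canon(factor.id, resolved)
            if not cid:
                raise CldError(f"factor {factor.id!r} normalizes to an empty label")
            raw = factor.raw_labels | {factor.id}
            if cid in factors:
                prior = factors[cid]
                factors[cid] = Factor(
                    id=cid,
                    raw_labels=prior.raw_labels | raw,
                    theme=prior.theme or factor.theme,
                    is_action_idea=prior.is_action_idea or factor.is_action_idea,
                )
            else:
                factors[cid] = Factor(
                    id=cid,
                    raw_labels=frozenset(raw),
                    theme=factor.theme,
                    is_action_idea=factor.is_action_idea,
                )
        edges: list[Edge] = []
        for edge in model.edges:
            cause = _canon(edge.cause, resolved)
            effect = _canon(edge.effect, resolved)
            if cause == effect:
                raise CldError(
                    f"canonicalization merges both endpoints of edge "
                    f"({edge.cause!r}, {edge.effect!r}, {edge.polarity.symbol}) "
                    f"into {cause!r}, creating a self-edge"
                )
            edges.append(replace(edge, cause=cause, effect=effect))
        out.append(
            GroupModel(
                group_id=model.group_id,
                factors=factors,
                edges=merge_duplicate_edges(edges),
                focal=_canon(model.focal, resolved),
            )
        )
    return out
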