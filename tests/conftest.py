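import numpy as np
import pytest

from cldkit.aggregate import AggregateEdge, AggregateModel
from cldkit.model import Edge, Factor, GroupModel, Polarity


def E(cause, effect, sign="+", delay=False, group="g1"):
    return Edge(
        cause=cause,
        effect=effect,
        polarity=Polarity.from_symbol(sign),
        delay=delay,
        group_id=group,
    )


def make_model(group_id, edges, focal, actions=()):
    """GroupModel from (cause, effect, sign[, delay]) tuples; factors inferred."""
    edge_set = {
        E(e[0], e[1], e[2] if len(e) > 2 else "+", e[3] if len(e) > 3 else False, group_id)
        for e in edges
    }
    labels = {e.cause for e in edge_set} | {e.effect for e in edge_set} | {focal}
    factors = {
        label: Factor(id=label, is_action_idea=label in actions) for label in labels
    }
    return GroupModel(group_id=group_id, factors=factors, edges=edge_set, focal=focal)


def make_aggregate(edge_supports, focal, n_groups=4, actions=()):
    """AggregateModel from {(cause, effect, sign): support}; groups g1..gN."""
    group_ids = [f"g{i + 1}" for i in range(n_groups)]
    edges = {}
    for (cause, effect, sign), support in edge_supports.items():
        key = (cause, effect, sign)
        edges[key] = AggregateEdge(
            cause=cause,
            effect=effect,
            polarity=Polarity.from_symbol(sign),
            supporting_groups=frozenset(group_ids[:support]),
            instance_count=support,
        )
    labels = {c for c, _, _ in edges} | {e for _, e, _ in edges} | {focal} | set(actions)
    factors = {l: Factor(id=l, is_action_idea=l in actions) for l in labels}
    return AggregateModel(group_ids=group_ids, factors=factors, edges=edges, focal=focal)


def random_signed_digraph(rng, max_nodes=5, p_edge=0.25):
    """Random edge triples over <= max_nodes nodes; both signs possible per pair."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = set()
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            if rng.random() < p_edge:
                edges.add((u, v, "+"))
            if rng.random() < p_edge:
                edges.add((u, v, "-"))
    return edges


@pytest.fixture
def triangle_model():
    """All-positive three-node feedback loop through the focal variable."""
    return make_model("g1", [("risk", "a", "+"), ("a", "b", "+"), ("b", "risk", "+")], "risk")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
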