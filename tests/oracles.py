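"""Independent brute-force oracles used to check the library.

Everything here is deliberately naive pure Python over plain tuples and
dicts — no networkx, no cldkit graph helpers — so the oracles cannot share
a defect with the implementation they check.

Edges are (cause, effect, sign) triples with sign in {"+", "-"}.
"""

from __future__ import annotations

import itertools

Triple = tuple[str, str, str]


def brute_force_cycles(
    edges: set[Triple], max_len: int | None = None
) -> set[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All simple directed cycles by testing every node subset and rotation.

    Returns {(node cycle in canonical rotation, sign sequence)}.  A node
    pair carrying both signs yields one entry per sign combination.
    """
    nodes = sorted({u for u, _, _ in edges} | {v for _, v, _ in edges})
    signs_of: dict[tuple[str, str], list[str]] = {}
    for u, v, s in edges:
        signs_of.setdefault((u, v), []).append(s)
    cap = len(nodes) if max_len is None else min(max_len, len(nodes))
    found = set()
    for k in range(2, cap + 1):
        for subset in itertools.combinations(nodes, k):
            first = subset[0]  # combinations are sorted: first is the minimum
            for perm in itertools.permutations(subset[1:]):
                cycle = (first,) + perm
                arcs = list(zip(cycle, cycle[1:] + cycle[:1]))
                if any(arc not in signs_of for arc in arcs):
                    continue
                for combo in itertools.product(*(sorted(signs_of[a]) for a in arcs)):
                    found.add((cycle, combo))
    return found


def cycle_edge_union(edges: set[Triple]) -> set[Triple]:
    """Edges appearing in at least one brute-force cycle."""
    union: set[Triple] = set()
    for cycle, combo in brute_force_cycles(edges):
        arcs = list(zip(cycle, cycle[1:] + cycle[:1]))
        for (u, v), s in zip(arcs, combo):
            union.add((u, v, s))
    return union


def _reachable(adjacency: dict[str, set[str]], start: str) -> set[str]:
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for succ in adjacency.get(node, ()):
            if succ not in seen:
                seen.add(succ)
                stack.append(succ)
    return seen


def focal_connected_edges(edges: set[Triple], focal: str) -> set[Triple]:
    """Edges on a directed path ending at or starting from focal (brute)."""
    fwd: dict[str, set[str]] = {}
    rev: dict[str, set[str]] = {}
    for u, v, _ in edges:
        fwd.setdefault(u, set()).add(v)
        rev.setdefault(v, set()).add(u)
    nodes = {u for u, _, _ in edges} | {v for _, v, _ in edges}
    if focal not in nodes:
        return set()
    ancestors = _reachable(rev, focal)
    descendants = _reachable(fwd, focal)
    return {(u, v, s) for u, v, s in edges if v in ancestors or u in descendants}


def cycle_member_edges(edges: set[Triple]) -> set[Triple]:
    """Edges on some simple cycle, by per-edge reachability: u->v is on a
    cycle iff some directed walk leads from v back to u (a walk back implies
    a simple path back, which closes a simple cycle through the edge)."""
    fwd: dict[str, set[str]] = {}
    for u, v, _ in edges:
        fwd.setdefault(u, set()).add(v)
    return {(u, v, s) for u, v, s in edges if u in _reachable(fwd, v)}


def core_filter(
    supports: dict[Triple, int], focal: str, min_support: int
) -> set[Triple]:
    """Brute-force consensus-core filter: support threshold, then repeated
    exhaustive cycle/focal-path qualification until nothing changes."""
    kept = {e for e, s in supports.items() if s >= min_support}
    while True:
        qualifying = cycle_member_edges(kept) | focal_connected_edges(kept, focal)
        surviving = kept & qualifying
        if surviving == kept:
            return kept
        kept = surviving


def bounded_paths(
    edges: set[Triple], start: str, max_edges: int
) -> set[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Every simple directed path of 1..max_edges edges from ``start``,
    as (node sequence, sign sequence) pairs — exhaustive DFS."""
    out_edges: dict[str, list[tuple[str, str]]] = {}
    for u, v, s in edges:
        out_edges.setdefault(u, []).append((v, s))
    found = set()

    def walk(path: tuple[str, ...], signs: tuple[str, ...]) -> None:
        if len(signs) >= max_edges:
            return
        for succ, sign in out_edges.get(path[-1], ()):
            if succ in path:
                continue
            found.add((path + (succ,), signs + (sign,)))
            walk(path + (succ,), signs + (sign,))

    walk((start,), ())
    return found
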