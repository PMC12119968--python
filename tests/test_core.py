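"""Consensus core extraction, focal connectivity, indirect-path consensus."""

import pytest

from cldkit.core import (
    EdgeReason,
    causal_connectivity,
    core_report,
    extract_core,
    indirect_path_consensus,
)
from cldkit.loops import build_graph
from cldkit.model import CldError, Polarity

from conftest import make_aggregate, make_model
from oracles import core_filter


def random_aggregate(rng, max_nodes=25):
    n = int(rng.integers(4, max_nodes + 1))
    nodes = [f"n{i:02d}" for i in range(n)]
    supports = {}
    for u in nodes:
        for v in nodes:
            if u == v or rng.random() > 0.08:
                continue
            sign = "-" if rng.random() < 0.3 else "+"
            supports[(u, v, sign)] = int(rng.integers(1, 5))
    return supports, nodes[0]


class TestExtractCore:
    def test_supported_focal_triangle_kept_as_both(self):
        agg = make_aggregate(
            {("f", "a", "+"): 2, ("a", "b", "+"): 2, ("b", "f", "+"): 2}, focal="f"
        )
        core = extract_core(agg, min_support=2)
        assert core.n_edges == 3 and core.n_nodes == 3
        assert set(core.reasons.values()) == {EdgeReason.BOTH}

    def test_low_support_edge_dropped_first(self):
        agg = make_aggregate(
            {("f", "a", "+"): 2, ("a", "b", "+"): 2, ("b", "f", "+"): 2, ("c", "a", "+"): 1},
            focal="f",
        )
        core = extract_core(agg, min_support=2)
        assert ("c", "a", "+") not in core.edges
        assert "c" not in core.nodes

    def test_disconnected_chain_removed_in_structural_step(self):
        agg = make_aggregate(
            {("f", "a", "+"): 2, ("a", "f", "+"): 2, ("x", "y", "+"): 2}, focal="f"
        )
        core = extract_core(agg, min_support=2)
        assert ("x", "y", "+") not in core.edges

    def test_cascading_removal_reaches_fixed_point(self):
        # chain into focal where the entry edge has support 1: once it is cut,
        # the rest of the chain loses its path to focal and must go too
        agg = make_aggregate(
            {("a", "b", "+"): 2, ("b", "c", "+"): 2, ("c", "f", "+"): 1,
             ("f", "z", "+"): 2, ("z", "f", "+"): 2},
            focal="f",
        )
        core = extract_core(agg, min_support=2)
        assert set(core.edges) == {("f", "z", "+"), ("z", "f", "+")}

    def test_exogenous_stub_nodes_dropped(self):
        agg = make_aggregate({("f", "a", "+"): 2, ("a", "f", "-"): 2}, focal="f")
        agg.factors["isolated"] = agg.factors["f"].__class__(id="isolated")
        core = extract_core(agg, min_support=2)
        assert "isolated" not in core.nodes

    def test_focal_absent_or_bad_support_rejected(self):
        agg = make_aggregate({("a", "b", "+"): 2}, focal="b")
        with pytest.raises(CldError):
            extract_core(agg, min_support=0)
        agg.focal = "ghost"
        with pytest.raises(CldError, match="focal"):
            extract_core(agg, min_support=2)

    def test_matches_brute_force_filter_on_random_aggregates(self, rng):
        for _ in range(100):
            supports, focal = random_aggregate(rng)
            agg = make_aggregate(supports, focal=focal)
            core = extract_core(agg, min_support=2)
            assert set(core.edges) == core_filter(supports, focal, min_support=2)

    def test_monotone_in_min_support_and_idempotent(self, rng):
        for _ in range(30):
            supports, focal = random_aggregate(rng, max_nodes=15)
            agg = make_aggregate(supports, focal=focal)
            previous = None
            for k in (1, 2, 3, 4):
                core = extract_core(agg, min_support=k)
                if previous is not None:
                    assert set(core.edges) <= previous
                previous = set(core.edges)
            core1 = extract_core(agg, min_support=2)
            re_agg = make_aggregate(
                {k: supports[k] for k in core1.edges}, focal=focal
            )
            core2 = extract_core(re_agg, min_support=2)
            assert set(core1.edges) == set(core2.edges)

    def test_identity_when_everything_qualifies(self):
        agg = make_aggregate(
            {("f", "a", "+"): 1, ("a", "b", "-"): 1, ("c", "f", "+"): 1}, focal="f"
        )
        core = extract_core(agg, min_support=1)
        assert set(core.edges) == set(agg.edges)


class TestCausalConnectivity:
    def graph(self, triples):
        return build_graph({(c, e, Polarity.from_symbol(s)) for c, e, s in triples})

    def test_ancestor_and_descendant_paths_qualify(self):
        g = self.graph([("a", "b", "+"), ("b", "f", "+"), ("f", "c", "+"), ("c", "d", "-")])
        assert causal_connectivity(g, "f") == {
            ("a", "b", "+"), ("b", "f", "+"), ("f", "c", "+"), ("c", "d", "-"),
        }

    def test_disconnected_component_excluded(self):
        g = self.graph([("a", "f", "+"), ("e", "x", "+")])
        assert causal_connectivity(g, "f") == {("a", "f", "+")}

    def test_missing_focal_gives_empty_set(self):
        assert causal_connectivity(self.graph([("a", "b", "+")]), "f") == set()


class TestIndirectConsensus:
    def test_witness_path_raises_effective_support(self):
        models = [
            make_model("g1", [("A", "C", "+")], "C"),
            make_model("g2", [("A", "B", "+"), ("B", "C", "+")], "C"),
        ]
        from cldkit.aggregate import union_models

        records = indirect_path_consensus(union_models(models), models)
        rec = next(r for r in records if (r.cause, r.effect) == ("A", "C"))
        assert rec.direct_groups == ("g1",)
        assert rec.effective_support == 2
        assert rec.indirect_groups[0][0] == "g2"
        assert rec.indirect_groups[0][1] == ("A", "B", "C")

    def test_sign_mismatched_path_is_no_witness(self):
        models = [
            make_model("g1", [("A", "C", "+")], "C"),
            make_model("g2", [("A", "B", "+"), ("B", "C", "-")], "C"),
        ]
        from cldkit.aggregate import union_models

        records = indirect_path_consensus(union_models(models), models)
        rec = next(r for r in records if (r.cause, r.effect) == ("A", "C"))
        assert rec.effective_support == 1 and rec.indirect_groups == ()

    def test_intermediate_cap_respected(self):
        models = [
            make_model("g1", [("A", "D", "+")], "D"),
            make_model("g2", [("A", "B", "+"), ("B", "C", "+"), ("C", "D", "+")], "D"),
        ]
        from cldkit.aggregate import union_models

        agg = union_models(models)
        rec = next(
            r for r in indirect_path_consensus(agg, models, max_intermediates=1)
            if (r.cause, r.effect) == ("A", "D")
        )
        assert rec.effective_support == 1
        rec = next(
            r for r in indirect_path_consensus(agg, models, max_intermediates=2)
            if (r.cause, r.effect) == ("A", "D")
        )
        assert rec.effective_support == 2

    def test_group_mismatch_rejected(self):
        models = [make_model("g1", [("A", "B", "+")], "B")]
        from cldkit.aggregate import union_models

        agg = union_models(models)
        with pytest.raises(CldError, match="absent"):
            indirect_path_consensus(agg, [], max_intermediates=2)

    def test_effective_support_matches_exhaustive_search(self, rng):
        from cldkit.aggregate import union_models
        from cldkit.synthetic import GenParams, generate_true_system, sample_group_models
        from oracles import bounded_paths

        params = GenParams(n_factors=40, n_core_edges=30, n_peripheral_edges=4,
                           noise_rate=5.0, n_action_nodes=4, seed=13)
        models = sample_group_models(generate_true_system(params), params)
        agg = union_models(models)
        records = indirect_path_consensus(agg, models, max_intermediates=2)
        group_edges = {
            m.group_id: {e.key for e in m.edges} for m in models
        }
        for rec in records[:40]:
            indirect = set()
            for gid, triples in group_edges.items():
                if gid in rec.direct_groups:
                    continue
                for nodes, signs in bounded_paths(triples, rec.cause, max_edges=3):
                    if nodes[-1] == rec.effect and len(nodes) >= 3:
                        if ("-" if signs.count("-") % 2 else "+") == rec.polarity.symbol:
                            indirect.add(gid)
                            break
            assert rec.effective_support == len(rec.direct_groups) + len(indirect)


class TestCoreReport:
    def test_triangle_report(self):
        agg = make_aggregate(
            {("f", "a", "+"): 2, ("a", "b", "+"): 2, ("b", "f", "+"): 2}, focal="f"
        )
        report = core_report(extract_core(agg, min_support=2))
        assert report["n_nodes"] == 3 and report["n_edges"] == 3
        assert report["loop_inventory"]["n_reinforcing"] == 1
        assert report["support_histogram"] == {"2": 3}

    def test_empty_core_report(self):
        agg = make_aggregate({("a", "b", "+"): 1}, focal="b")
        report = core_report(extract_core(agg, min_support=2))
        assert report["n_nodes"] == 0 and report["n_edges"] == 0
        assert report["loop_inventory"]["loops"] == []
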