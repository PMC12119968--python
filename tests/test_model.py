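"""Domain types, label standardization, and edge deduplication."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cldkit.model import (
    CldError,
    Edge,
    Factor,
    GroupModel,
    Polarity,
    canonicalize_labels,
    merge_duplicate_edges,
    normalize_label,
    validate_group_model,
)

from conftest import E, make_model


class TestPolarity:
    def test_symbols_round_trip(self):
        assert Polarity.from_symbol("+") is Polarity.POSITIVE
        assert Polarity.from_symbol("-") is Polarity.NEGATIVE
        assert Polarity.POSITIVE.symbol == "+"
        with pytest.raises(CldError):
            Polarity.from_symbol("pos")

    def test_product_rules(self):
        P, N = Polarity.POSITIVE, Polarity.NEGATIVE
        assert P * P is P and P * N is N and N * P is N and N * N is P

    @given(st.lists(st.sampled_from(list(Polarity)), max_size=12))
    @settings(derandomize=True)
    def test_product_is_negative_parity(self, signs):
        expected = (
            Polarity.NEGATIVE
            if sum(s is Polarity.NEGATIVE for s in signs) % 2
            else Polarity.POSITIVE
        )
        assert Polarity.product(signs) is expected


class TestNormalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Health Literacy", "health_literacy"),
            ("  health   literacy ", "health_literacy"),
            ("Social Isolation", "social_isolation"),
            ("TRAUMA", "trauma"),
        ],
    )
    def test_default_rule(self, raw, expected):
        assert normalize_label(raw) == expected


class TestCanonicalize:
    def test_synonyms_merge_factors_and_raw_labels(self):
        model = make_model("g1", [("Health Literacy", "risk", "+")], "risk")
        model.factors["health literacy "] = Factor(id="health literacy ")
        out = canonicalize_labels(
            [model], {"Health Literacy": "health_literacy", "health literacy ": "health_literacy"}
        )[0]
        assert "health_literacy" in out.factors
        assert {"Health Literacy", "health literacy "} <= out.factors["health_literacy"].raw_labels

    def test_empty_map_applies_default_normalization(self):
        model = make_model("g1", [("Social Isolation", "Risk", "+")], "Risk")
        out = canonicalize_labels([model])[0]
        assert set(out.factors) == {"social_isolation", "risk"}
        (edge,) = out.edges
        assert (edge.cause, edge.effect) == ("social_isolation", "risk")

    def test_action_flags_or_ed_on_merge(self):
        model = make_model("g1", [("A", "risk", "+"), ("B", "risk", "+")], "risk", actions={"B"})
        out = canonicalize_labels([model], {"A": "x", "B": "x"})[0]
        assert out.factors["x"].is_action_idea

    def test_map_collapsing_edge_endpoints_is_an_error(self):
        model = make_model("g1", [("A", "B", "+"), ("B", "risk", "+")], "risk")
        with pytest.raises(CldError, match="'A'.*'B'|self-edge"):
            canonicalize_labels([model], {"A": "x", "B": "x"})

    def test_duplicate_edges_collapse_after_merging(self):
        model = make_model(
            "g1", [("A", "risk", "+", True), ("B", "risk", "+", False)], "risk"
        )
        out = canonicalize_labels([model], {"A": "x", "B": "x"})[0]
        (edge,) = out.edges
        assert edge.cause == "x" and edge.delay  # delay OR-ed across collapsed pair

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["A", "B", "C", "D", "risk"]),
                st.sampled_from(["A", "B", "C", "D", "risk"]),
                st.sampled_from(["+", "-"]),
            ).filter(lambda t: t[0] != t[1]),
            min_size=1,
            max_size=12,
        )
    )
    @settings(derandomize=True)
    def test_idempotent_and_edge_preserving(self, triples):
        model = make_model("g1", triples, "risk")
        once = canonicalize_labels([model])
        twice = canonicalize_labels(once)
        assert {e.key for e in once[0].edges} == {e.key for e in twice[0].edges}
        assert once[0].factors.keys() == twice[0].factors.keys()
        # total causal content preserved: every input identity maps to one output identity
        expected = {(a.lower(), b.lower(), s) for a, b, s in triples}
        assert {e.key for e in once[0].edges} == expected


class TestMergeDuplicates:
    def test_delay_flag_or_ed(self):
        merged = merge_duplicate_edges([E("A", "B", "+", False), E("A", "B", "+", True)])
        (edge,) = merged
        assert edge.delay

    def test_opposite_signs_are_distinct_identities(self):
        merged = merge_duplicate_edges([E("A", "B", "+"), E("A", "B", "-")])
        assert {e.polarity.symbol for e in merged} == {"+", "-"}

    def test_empty_input(self):
        assert merge_duplicate_edges([]) == set()

    def test_mixed_groups_rejected(self):
        with pytest.raises(CldError, match="mixed group_ids"):
            merge_duplicate_edges([E("A", "B", group="g1"), E("A", "C", group="g2")])


class TestValidation:
    def test_valid_triangle_is_clean(self, triangle_model):
        assert validate_group_model(triangle_model) == []

    def test_missing_focal_reported(self, triangle_model):
        triangle_model.focal = "nowhere"
        codes = [v.code for v in validate_group_model(triangle_model)]
        assert "focal-missing" in codes

    def test_dangling_edge_endpoint_reported(self, triangle_model):
        triangle_model.edges.add(E("a", "ghost"))
        report = validate_group_model(triangle_model)
        assert any(v.code == "edge-endpoint-missing" and "ghost" in v.message for v in report)

    def test_foreign_group_edge_reported(self, triangle_model):
        triangle_model.edges.add(E("a", "b", group="g9"))
        assert any(v.code == "edge-group-mismatch" for v in validate_group_model(triangle_model))

    def test_self_edges_rejected_at_construction(self):
        with pytest.raises(CldError, match="self-edge"):
            Edge(cause="A", effect="A", polarity=Polarity.POSITIVE)
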