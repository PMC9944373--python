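"""Data model: estimate aggregation, validation, pruning and exclusion."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import stpra
from stpra.model import AndPolicy, Provenance, SourceEstimate

from conftest import build_tree


def src(v, prov="literature"):
    return SourceEstimate(value=v, provenance=Provenance(prov))


class TestAggregateEstimates:
    @pytest.mark.parametrize(
        "values, low, average, high",
        [
            ([0.2, 0.3, 0.7], 0.25, 0.4, 0.5),   # drop-max / mean / drop-min
            ([0.4], 0.4, 0.4, 0.4),              # single source collapses
            ([0.1, 0.1, 0.1], 0.1, 0.1, 0.1),    # ties: one instance removed
            ([0.0, 1.0], 0.0, 0.5, 1.0),
        ],
    )
    def test_low_average_high_rule(self, values, low, average, high):
        est = stpra.aggregate_estimates([src(v) for v in values])
        assert est.low == pytest.approx(low)
        assert est.average == pytest.approx(average)
        assert est.high == pytest.approx(high)

    def test_literature_shadows_expert(self):
        est = stpra.aggregate_estimates([src(0.1, "literature"), src(0.9, "expert")])
        assert est.average == pytest.approx(0.1)

    def test_expert_used_when_no_literature(self):
        est = stpra.aggregate_estimates([src(0.9, "expert"), src(0.7, "expert")])
        assert est.average == pytest.approx(0.8)

    def test_empty_sources_is_unestimated(self):
        est = stpra.aggregate_estimates([])
        assert not est.is_estimated

    def test_out_of_domain_value_rejected(self):
        with pytest.raises(stpra.DomainError):
            stpra.aggregate_estimates([src(1.5)])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    def test_ordering_invariant(self, values):
        est = stpra.aggregate_estimates([src(v) for v in values])
        assert est.low <= est.average <= est.high
        assert 0.0 <= est.low and est.high <= 1.0


class TestValidate:
    def test_valid_tree_has_no_issues(self):
        t = build_tree(
            {"TOP": ("OR", ["G1", "G2"]), "G1": ("AND", ["A", "B"]), "G2": ("OR", ["B", "C"])},
            {"A": 0.1, "B": 0.2, "C": 0.3},
        )
        assert stpra.validate(t) == []

    def test_cycle_detected(self):
        t = stpra.FaultTree(
            name="c", top="G1",
            gates=(stpra.Gate("G1", "OR", ("G2", "A")), stpra.Gate("G2", "OR", ("G1", "A"))),
            events=(stpra.BasicEvent("A"),),
        )
        assert any(i.code == "cycle" and i.severity == "error" for i in stpra.validate(t))

    def test_unreachable_event_is_warning(self):
        t = stpra.FaultTree(
            name="u", top="TOP",
            gates=(stpra.Gate("TOP", "OR", ("A", "B")),),
            events=(stpra.BasicEvent("A"), stpra.BasicEvent("B"), stpra.BasicEvent("Z")),
        )
        issues = [i for i in stpra.validate(t) if i.code == "unreachable"]
        assert [i.subject_id for i in issues] == ["Z"]
        assert all(i.severity == "warning" for i in issues)

    def test_dangling_reference_is_error(self):
        t = stpra.FaultTree(
            name="d", top="TOP",
            gates=(stpra.Gate("TOP", "OR", ("A", "X")),),
            events=(stpra.BasicEvent("A"),),
        )
        assert any(i.code == "dangling" and i.subject_id == "X" for i in stpra.validate(t))

    def test_idempotent_and_deterministic(self):
        t = stpra.FaultTree(
            name="d", top="TOP",
            gates=(stpra.Gate("TOP", "OR", ("A",)),),
            events=(stpra.BasicEvent("A"), stpra.BasicEvent("Z")),
        )
        assert stpra.validate(t) == stpra.validate(t)


class TestPruneAndExclude:
    def test_prune_removes_unestimated_or_leaf(self):
        t = build_tree({"TOP": ("OR", ["A", "B"])}, {"A": 0.1, "B": None})
        pruned, removed = stpra.prune_unestimated(t)
        assert removed == ["B"]
        assert set(pruned.event_map) == {"A"}

    def test_prune_identity_when_all_estimated(self):
        t = build_tree({"TOP": ("OR", ["A", "B"])}, {"A": 0.1, "B": 0.2})
        pruned, removed = stpra.prune_unestimated(t)
        assert removed == []
        assert pruned == t

    def test_prune_refuses_to_gut_and_gate(self):
        t = build_tree({"TOP": ("AND", ["A", "B"])}, {"A": 0.1, "B": None})
        with pytest.raises(stpra.StructuralError, match="TOP"):
            stpra.prune_unestimated(t)

    def test_exclude_or_leaf(self):
        t = build_tree({"TOP": ("OR", ["A", "B"])}, {"A": 0.1, "B": 0.2})
        out = stpra.exclude_events(t, {"B"})
        assert set(out.event_map) == {"A"}
        assert out.gate("TOP").inputs == ("A",)

    def test_exclude_cascades_empty_or_into_and_parent_raises(self):
        t = build_tree(
            {"TOP": ("AND", ["G1", "G2"]), "G1": ("OR", ["A"]), "G2": ("OR", ["B", "C"])},
            {"A": 0.1, "B": 0.2, "C": 0.3},
        )
        with pytest.raises(stpra.StructuralError):
            stpra.exclude_events(t, {"A"}, AndPolicy.forbid)

    def test_neutralize_pins_and_conjunct_to_one(self):
        t = build_tree({"TOP": ("AND", ["A", "B"])}, {"A": 0.3, "B": 0.5})
        out = stpra.exclude_events(t, {"B"}, AndPolicy.neutralize)
        assert stpra.top_probability_exact(out).exact == pytest.approx(0.3)

    def test_exclude_unknown_id_raises(self):
        t = build_tree({"TOP": ("OR", ["A", "B"])}, {"A": 0.1, "B": 0.2})
        with pytest.raises(stpra.StructuralError, match="nope"):
            stpra.exclude_events(t, {"nope"})

    def test_or_exclusion_never_raises_top_probability(self):
        # coherence: removing a failure path cannot make failure likelier
        for seed in range(10):
            cfg = stpra.GeneratorConfig(
                n_events=8, n_gates=3, and_fraction=0.0, repeat_rate=0.2, seed=seed
            )
            t = stpra.generate_tree(cfg)
            base = stpra.top_probability_exact(t).exact
            victim = sorted(t.event_map)[0]
            try:
                reduced = stpra.exclude_events(t, {victim})
            except stpra.StructuralError:
                continue
            assert stpra.top_probability_exact(reduced).exact <= base + 1e-12
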