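"""Importance measures and the low/high and leave-out sensitivity analyses."""

import pytest

import stpra
from stpra.importance import DegenerateModelError

from conftest import build_tree, small_configs


class TestImportanceAll:
    def test_and_gate_makes_every_leaf_fully_critical(self):
        t = build_tree({"TOP": ("AND", ["A", "B"])}, {"A": 0.3, "B": 0.7})
        recs = {r.event_id: r for r in stpra.importance_all(t)}
        assert recs["A"].criticality == pytest.approx(1.0)
        assert recs["B"].criticality == pytest.approx(1.0)
        assert recs["A"].fussell_vesely == pytest.approx(1.0)

    def test_worked_tree_fussell_vesely(self, worked_tree):
        recs = {r.event_id: r for r in stpra.importance_all(worked_tree)}
        assert recs["B"].fussell_vesely == pytest.approx(0.1 / 0.109, abs=1e-9)
        # A appears only in {A,C}: FV = 0.01/0.109
        assert recs["A"].fussell_vesely == pytest.approx(0.01 / 0.109, abs=1e-9)

    def test_irrelevant_event_scores_zero(self):
        # C only ever occurs alongside the already-sufficient B? No — make C
        # genuinely irrelevant: TOP=OR(A, AND(A, C)) absorbs C entirely.
        t = build_tree(
            {"TOP": ("OR", ["A", "G1"]), "G1": ("AND", ["A", "C"])},
            {"A": 0.2, "C": 0.4},
        )
        recs = {r.event_id: r for r in stpra.importance_all(t)}
        assert recs["C"].birnbaum == pytest.approx(0.0, abs=1e-12)
        assert recs["C"].criticality == pytest.approx(0.0, abs=1e-12)
        assert recs["C"].fussell_vesely == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_model_raises(self):
        t = build_tree({"TOP": ("OR", ["A"])}, {"A": 0.0})
        with pytest.raises(DegenerateModelError):
            stpra.importance_all(t)

    def test_birnbaum_equals_finite_difference(self):
        # the structure polynomial is multilinear, so a central difference
        # at any h reproduces the pinned-probability derivative exactly
        h = 0.01
        for cfg in small_configs(8):
            t = stpra.generate_tree(cfg)
            probs = t.leaf_probabilities()
            recs = {r.event_id: r for r in stpra.importance_all(t)}
            gates = {g.id: (g.kind.value, list(g.inputs)) for g in t.gates}

            def top_at(eid, p):
                shifted = build_tree(gates, {**probs, eid: p})
                return stpra.top_probability_exact(shifted).exact

            for eid in list(probs)[:3]:
                p = probs[eid]
                if not (h <= p <= 1 - h):
                    continue
                fd = (top_at(eid, p + h) - top_at(eid, p - h)) / (2 * h)
                assert recs[eid].birnbaum == pytest.approx(fd, abs=1e-6)

    def test_coherent_inequalities_on_synthetic_suite(self):
        for cfg in small_configs(20):
            t = stpra.generate_tree(cfg)
            recs = stpra.importance_all(t)
            assert sum(r.fussell_vesely for r in recs) >= 1.0 - 1e-9
            for r in recs:
                assert r.birnbaum >= -1e-12
                assert r.criticality <= r.fussell_vesely + 1e-9

    def test_invariant_under_round_trip(self, worked_tree):
        again = stpra.parse_model(stpra.serialize_model(worked_tree))
        a = stpra.importance_all(worked_tree)
        b = stpra.importance_all(again)
        assert a == b


class TestRanking:
    def test_descending_with_id_ties(self):
        mk = lambda e, c: stpra.ImportanceRecord(e, 0.1, 0.1, c, c)
        recs = [mk("x", 0.209765), mk("b", 0.345884), mk("a", 0.334611), mk("c", 0.334611)]
        ranked = stpra.rank_events(recs, "criticality")
        assert [r.event_id for r in ranked] == ["b", "a", "c", "x"]

    def test_empty_input(self):
        assert stpra.rank_events([], "birnbaum") == []

    def test_unknown_measure(self):
        with pytest.raises(ValueError):
            stpra.rank_events([], "magic")


class TestSensitivity:
    def test_bound_rows_monotone_and_match_aggregation(self):
        t = build_tree({"TOP": ("OR", ["A"])}, {"A": [0.2, 0.3, 0.7]})
        table = stpra.bound_analysis(t)
        by_label = {r.label: r.top_probability for r in table.rows}
        assert by_label["low"] == pytest.approx(0.25)
        assert by_label["average"] == pytest.approx(0.4)
        assert by_label["high"] == pytest.approx(0.5)

    def test_single_source_leaves_collapse_bounds(self):
        t = build_tree({"TOP": ("OR", ["A", "B"])}, {"A": 0.1, "B": 0.2})
        vals = [r.top_probability for r in stpra.bound_analysis(t).rows]
        assert vals[0] == vals[1] == vals[2]

    def test_bounds_monotone_on_synthetic_suite(self):
        for cfg in small_configs(20):
            t = stpra.generate_tree(cfg)
            low, avg, high = [r.top_probability for r in stpra.bound_analysis(t).rows]
            assert low <= avg + 1e-12 and avg <= high + 1e-12

    def test_leave_out_baseline_and_delta(self):
        t = build_tree({"TOP": ("OR", ["A", "B"])}, {"A": 0.1, "B": 0.1})
        table = stpra.leave_out_analysis(t, [("no B", {"B"}), ("nothing", set())])
        rows = {r.label: r for r in table.rows}
        assert rows["baseline"].top_probability == pytest.approx(0.19)
        assert rows["no B"].top_probability == pytest.approx(0.1)
        assert rows["no B"].delta_vs_baseline == pytest.approx(-0.09)
        assert rows["nothing"].delta_vs_baseline == 0.0

    def test_illegal_exclusion_propagates(self):
        t = build_tree({"TOP": ("AND", ["A", "B"])}, {"A": 0.1, "B": 0.1})
        with pytest.raises(stpra.StructuralError):
            stpra.leave_out_analysis(t, [("bad", {"B"})])
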