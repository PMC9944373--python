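# stpra — sociotechnical probabilistic risk assessment with fault trees

`stpra` is a fault-tree analysis toolkit for prospective patient-safety risk
modelling (sociotechnical probabilistic risk assessment, ST-PRA). It was
built around one concrete application — the risk of a patient fall inside a
psychiatric seclusion room — but the engine is generic: any adverse outcome
modelled as AND/OR Boolean logic over elicited risk factors can be analysed.

It is aimed at patient-safety researchers and reliability engineers who want
the standard PRA quantities from an elicited model without commercial
software: minimal cut sets, exact and approximate top-event probabilities,
importance rankings, and the sensitivity analyses that elicitation-based
models need (low/average/high source bounds, leave-one-out of contested
factors).

## The model

A fault tree is a DAG with one *top event* (the adverse outcome) over
*basic events* (risk factors) with occurrence probabilities `p_i`, combined
by gates. Under independence:

- AND gate: `P = ∏ p_i`
- OR gate: `P = 1 − ∏ (1 − p_i)` (the sum with every overlap subtracted)

A *minimal cut set* is an inclusion-minimal set of risk factors whose joint
occurrence forces the top event — a "critical path" to harm. `stpra`
enumerates them by top-down MOCUS expansion with Boolean absorption. The
exact top-event probability `Q` handles *repeated events* (a factor feeding
several gates) by Shannon decomposition, `Q = p_e·Q(e=1) + (1−p_e)·Q(e=0)`,
and is cross-reported with the rare-event sum `Σ P(Cᵢ)` and the min-cut
upper bound `1 − ∏(1 − P(Cᵢ))`, which bound it from above.

Per-factor importance is reported three ways: Birnbaum `B_e = Q(p_e=1) −
Q(p_e=0)`, criticality importance `B_e·p_e / Q` (what commercial PRA tools
label "criticality"), and Fussell–Vesely `P(∪ cut sets containing e) / Q`.

Each risk factor's probability is aggregated from elicited sources.
Literature values shadow expert values; the average estimate is their mean,
the low estimate is the mean without one instance of the highest value, and
the high estimate the mean without one instance of the lowest — the bounds
used by the sensitivity analysis.

## Worked example

The classic repeated-event tree — `TOP = AND(OR(A,B), OR(B,C))` with every
probability 0.1:

```python
import stpra

doc = """{"name": "worked", "top": "TOP",
 "gates": [{"id": "TOP", "kind": "AND", "inputs": ["G1", "G2"]},
           {"id": "G1", "kind": "OR", "inputs": ["A", "B"]},
           {"id": "G2", "kind": "OR", "inputs": ["B", "C"]}],
 "events": [{"id": "A", "sources": [{"value": 0.1}]},
            {"id": "B", "sources": [{"value": 0.1}]},
            {"id": "C", "sources": [{"value": 0.1}]}]}"""
tree = stpra.parse_model(doc)

print([sorted(c.events) for c in stpra.mocus_cut_sets(tree)])
r = stpra.top_probability_exact(tree)
print(r.exact, r.rare_event_sum, r.method)
fv = {x.event_id: x.fussell_vesely for x in stpra.importance_all(tree)}
print(fv["B"])
```

prints

```
[['B'], ['A', 'C']]
0.109 0.11000000000000001 factoring
0.9174311926605505
```

`{B}` alone forces the top event (it appears in both OR branches), so the
exact probability is `P(B ∪ (A∧C)) = 0.1 + 0.01 − 0.001 = 0.109` — not the
0.0361 a naive bottom-up multiplication of the two ORs would give — and B
is involved in 91.7% of all failures.

The packaged seclusion-falls reconstruction works the same way:

```python
skeleton = stpra.load_seclusion_skeleton()
report = stpra.build_report(skeleton, top_k=5)
print(report.to_text())
```

Its probabilities are an illustrative overlay (flagged in the model
metadata and every report); the structure encodes the published critical-
path architecture, in which a fall requires a disorder, a mechanism, a
reason, and failure of both risk assessment and prevention intervention.

A CLI mirrors the library: `stpra generate | cutsets | analyze | simulate |
importance | sensitivity | report | skeleton | validate` (see `--help`).

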