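import json

import pytest

import stpra


def build_tree(gates, event_probs, name="fixture"):
    """Compact tree builder: gates as {id: (kind, [inputs])}, events as {id: p or [p...]}."""
    doc = {
        "name": name,
        "top": next(iter(gates)),
        "gates": [
            {"id": gid, "kind": kind, "inputs": list(inputs)}
            for gid, (kind, inputs) in gates.items()
        ],
        "events": [
            {
                "id": eid,
                "sources": [
                    {"value": v, "provenance": "literature"}
                    for v in (
                        [] if p is None else p if isinstance(p, (list, tuple)) else [p]
                    )
                ],
            }
            for eid, p in event_probs.items()
        ],
    }
    return stpra.parse_model(json.dumps(doc))


@pytest.fixture
def worked_tree():
    """Repeated-event reference tree: TOP=AND(OR(A,B), OR(B,C)), all p=0.1."""
    return build_tree(
        {"TOP": ("AND", ["G1", "G2"]), "G1": ("OR", ["A", "B"]), "G2": ("OR", ["B", "C"])},
        {"A": 0.1, "B": 0.1, "C": 0.1},
    )


def small_configs(n, repeat_rate=0.3, max_events=12):
    """Deterministic family of generator configs with <= max_events leaves."""
    configs = []
    for seed in range(n):
        n_events = 4 + seed % (max_events - 3)
        n_gates = 2 + seed % 4
        configs.append(
            stpra.GeneratorConfig(
                n_events=n_events,
                n_gates=n_gates,
                and_fraction=0.34,
                max_fanin=8,
                repeat_rate=repeat_rate,
                sources_per_event=(1, 3),
                seed=seed,
            )
        )
    return configs
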