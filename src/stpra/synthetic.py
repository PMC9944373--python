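"""Random coherent fault trees with elicited-style probability sources.

The generator emulates the shape of an elicited patient-safety fault tree:
a single top event over a few dozen AND/OR gates and leaves, leaf
probabilities in the rare-to-moderate range, and several per-leaf source
estimates with literature/expert provenance so the aggregation and
low/average/high machinery is exercised end to end. Generation is
top-down — a gate skeleton is built first and leaves attached afterwards —
which guarantees every node is reachable from the top; repeated events are
added by wiring an existing leaf into a second gate with probability
``repeat_rate``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from typing import Optional

from .model import (
    BasicEvent,
    FaultTree,
    FaultTreeError,
    Gate,
    GateKind,
    Provenance,
    SourceEstimate,
    Theme,
    aggregate_estimates,
)


class ConfigError(FaultTreeError):
    """The generator configuration is infeasible or out of range."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the random-tree generator.

    Defaults mirror a moderate elicited model: mostly OR logic with a couple
    of conjunctions, leaf probabilities uniform on (0.01, 0.5) — fall risk
    factors are rare-to-moderate events — and 1–4 sources per factor with a
    30% chance each source is expert judgement rather than literature.
    """

    n_events: int = 20
    n_gates: int = 6
    and_fraction: float = 2 / 24
    max_fanin: int = 8
    repeat_rate: float = 0.1
    prob_dist: tuple = ("uniform", 0.01, 0.5)
    sources_per_event: tuple[int, int] = (1, 4)
    expert_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1 or self.n_gates < 1:
            raise ConfigError("n_events and n_gates must be >= 1")
        if not 0.0 <= self.and_fraction <= 1.0:
            raise ConfigError("and_fraction must lie in [0, 1]")
        if self.max_fanin < 2:
            raise ConfigError("max_fanin must be >= 2")
        if not 0.0 <= self.repeat_rate <= 1.0:
            raise ConfigError("repeat_rate must lie in [0, 1]")
        if not 0.0 <= self.expert_fraction <= 1.0:
            raise ConfigError("expert_fraction must lie in [0, 1]")
        lo, hi = self.sources_per_event
        if not (0 <= lo <= hi):
            raise ConfigError("sources_per_event must be a non-decreasing pair >= 0")
        kind = self.prob_dist[0]
        if kind == "uniform":
            _, a, b = self.prob_dist
            if not (0.0 <= a <= b <= 1.0):
                raise ConfigError("uniform bounds must satisfy 0 <= lo <= hi <= 1")
        elif kind == "beta":
            _, a, b = self.prob_dist
            if a <= 0 or b <= 0:
                raise ConfigError("beta parameters must be positive")
        else:
            raise ConfigError(f"unknown prob_dist kind {kind!r}")
        # Feasibility: (n_gates - 1) gate-child slots + n_events leaf slots
        # must fit in n_gates * max_fanin input slots.
        if (self.n_gates - 1) + self.n_events > self.n_gates * self.max_fanin:
            raise ConfigError(
                f"infeasible: {self.n_gates} gates with max_fanin={self.max_fanin} "
                f"cannot host {self.n_events} leaves"
            )


def _draw_probability(rng: random.Random, prob_dist: tuple) -> float:
    kind = prob_dist[0]
    if kind == "uniform":
        _, a, b = prob_dist
        return rng.uniform(a, b)
    _, a, b = prob_dist
    v = rng.betavariate(a, b)
    # keep strictly inside (0, 1) so leaves stay genuinely random
    return min(max(v, 1e-9), 1.0 - 1e-9)


def generate_sources(
    config: GeneratorConfig, event_count: int, rng: Optional[random.Random] = None
) -> list[list[SourceEstimate]]:
    """Per-event source lists with literature/expert provenance; seeded."""
    if rng is None:
        rng = random.Random(config.seed)
    lo, hi = config.sources_per_event
    out = []
    for i in range(event_count):
        k = rng.randint(lo, hi)
        sources = []
        for j in range(k):
            prov = (
                Provenance.expert
                if rng.random() < config.expert_fraction
                else Provenance.literature
            )
            sources.append(
                SourceEstimate(
                    value=_draw_probability(rng, config.prob_dist),
                    provenance=prov,
                    citation_label=f"synthetic-{prov.value}-{i}-{j}",
                )
            )
        out.append(sources)
    return out


def generate_tree(config: GeneratorConfig) -> FaultTree:
    """Generate a valid coherent fault tree; reproducible from the seed.

    Exactly ``n_gates`` gates (``round(and_fraction * n_gates)`` of them
    AND) and ``n_events`` basic events; every leaf reachable from the top.
    """
    rng = random.Random(config.seed)
    n_and = round(config.and_fraction * config.n_gates)

    gate_ids = [f"G{i}" for i in range(config.n_gates)]
    and_ids = set(rng.sample(gate_ids, n_and)) if n_and else set()

    # Skeleton: each non-top gate attaches under an earlier gate with
    # remaining fan-in capacity, keeping the graph a tree of gates.
    children: dict[str, list[str]] = {gid: [] for gid in gate_ids}
    for i, gid in enumerate(gate_ids[1:], start=1):
        candidates = [
            g for g in gate_ids[:i] if len(children[g]) < config.max_fanin
        ]
        if not candidates:
            raise ConfigError("infeasible: no gate has spare fan-in for the skeleton")
        parent = rng.choice(candidates)
        children[parent].append(gid)

    # Leaves: childless gates first (every gate needs >= 1 input), then the
    # remainder spread over gates with spare capacity.
    event_ids = [f"E{i}" for i in range(config.n_events)]
    pool = list(event_ids)
    rng.shuffle(pool)
    childless = [g for g in gate_ids if not children[g]]
    if len(pool) < len(childless):
        raise ConfigError("infeasible: fewer events than childless gates")
    for gid in childless:
        children[gid].append(pool.pop())
    while pool:
        candidates = [g for g in gate_ids if len(children[g]) < config.max_fanin]
        if not candidates:
            raise ConfigError("infeasible: fan-in exhausted while placing leaves")
        children[rng.choice(candidates)].append(pool.pop())

    # Repeats: wire a leaf into one extra gate that does not already see it.
    if config.repeat_rate > 0:
        for eid in event_ids:
            if rng.random() >= config.repeat_rate:
                continue
            candidates = [
                g
                for g in gate_ids
                if eid not in children[g] and len(children[g]) < config.max_fanin
            ]
            if candidates:
                children[rng.choice(candidates)].append(eid)

    gates = tuple(
        Gate(
            id=gid,
            kind=GateKind.AND if gid in and_ids else GateKind.OR,
            inputs=tuple(children[gid]),
        )
        for gid in gate_ids
    )

    themes = list(Theme)
    source_lists = generate_sources(config, config.n_events, rng)
    events = tuple(
        BasicEvent(
            id=eid,
            label=f"synthetic risk factor {eid}",
            theme=rng.choice(themes),
            estimate=aggregate_estimates(source_lists[i]),
            underdeveloped=rng.random() < 0.12,
        )
        for i, eid in enumerate(event_ids)
    )

    tree = FaultTree(
        name=f"synthetic-{config.seed}",
        top=gate_ids[0],
        gates=gates,
        events=events,
        metadata={"synthetic": True, "seed": config.seed},
    )
    return tree.require_valid()
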