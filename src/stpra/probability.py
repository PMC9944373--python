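"""Top-event and gate probabilities.

Under independent basic events, an AND gate's probability is the product of
its inputs and an OR gate's is ``1 - prod(1 - p_i)`` — the "overlap
subtracted" form of inclusion–exclusion. Plain bottom-up evaluation of
these formulas is exact only when no basic event reaches a gate along two
different paths; with repeated events the engine pivots on them by Shannon
decomposition: ``P = p_e * P(tree | e certain) + (1-p_e) * P(tree | e
impossible)``, recursing until every remaining repeated event is a
constant. Two standard cut-set approximations (rare-event sum and the
min-cut upper bound, MCUB) and a seeded Monte Carlo oracle are co-reported
so the exact number can always be cross-examined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import DomainError, FaultTree, GateKind, UnestimatedError
from .cutsets import CutSetCollection, mocus_cut_sets

SELECTORS = ("low", "average", "high")


@dataclass(frozen=True)
class TopEventResult:
    """Exact top-event probability with its standard upper-bound approximations."""

    exact: float
    rare_event_sum: float
    mcub: float
    method: str  # "bottom_up" | "factoring"
    estimate_selector: str
    rare_event_exceeds_one: bool = False
    n_minimal_cut_sets: int = 0


def structure_eval(tree: FaultTree, assignment: Mapping[str, bool]) -> bool:
    """Evaluate the Boolean structure function at one assignment."""
    missing = set(tree.event_map) - set(assignment)
    if missing:
        raise DomainError(f"assignment missing events: {sorted(missing)}")
    gmap = tree.gate_map
    cache: dict[str, bool] = {}

    def value(node: str) -> bool:
        if node in cache:
            return cache[node]
        gate = gmap.get(node)
        if gate is None:
            result = bool(assignment[node])
        elif gate.kind is GateKind.AND:
            result = all(value(i) for i in gate.inputs)
        else:
            result = any(value(i) for i in gate.inputs)
        cache[node] = result
        return result

    return value(tree.top)


def gate_probability(kind: GateKind | str, input_probs: Sequence[float]) -> float:
    """Combine independent input probabilities through one gate."""
    kind = GateKind(kind)
    for p in input_probs:
        if not 0.0 <= p <= 1.0:
            raise DomainError(f"input probability {p} outside [0, 1]")
    if kind is GateKind.AND:
        return math.prod(input_probs)
    return 1.0 - math.prod(1.0 - p for p in input_probs)


def _path_counts(tree: FaultTree) -> dict[str, int]:
    """Number of distinct top-to-node paths for every node (repeat detector)."""
    gmap = tree.gate_map
    counts: dict[str, int] = {}

    def walk(node: str, mult: int) -> None:
        counts[node] = counts.get(node, 0) + mult
        gate = gmap.get(node)
        if gate is not None:
            for inp in gate.inputs:
                walk(inp, mult)

    walk(tree.top, 1)
    return counts


def _bottom_up(tree: FaultTree, probs: Mapping[str, float], root: str) -> float:
    gmap = tree.gate_map
    cache: dict[str, float] = {}

    def value(node: str) -> float:
        if node in cache:
            return cache[node]
        gate = gmap.get(node)
        if gate is None:
            p = probs[node]
        else:
            p = gate_probability(gate.kind, [value(i) for i in gate.inputs])
        cache[node] = p
        return p

    return value(root)


def _exact(tree: FaultTree, probs: dict[str, float], root: str) -> tuple[float, str]:
    """Exact probability of the subtree at ``root``; returns (value, method)."""
    counts = _path_counts(tree) if root == tree.top else _subtree_counts(tree, root)
    repeated = [
        (eid, n) for eid, n in counts.items()
        if n > 1 and not tree.is_gate(eid) and 0.0 < probs[eid] < 1.0
    ]
    if not repeated:
        return _bottom_up(tree, probs, root), "bottom_up"
    # Pivot on the most frequently repeated event; ties broken by id so the
    # recursion order (and hence rounding) is reproducible.
    repeated.sort(key=lambda t: (-t[1], t[0]))
    pivot = repeated[0][0]
    p = probs[pivot]
    hi, _ = _exact(tree, {**probs, pivot: 1.0}, root)
    lo, _ = _exact(tree, {**probs, pivot: 0.0}, root)
    return p * hi + (1.0 - p) * lo, "factoring"


def _subtree_counts(tree: FaultTree, root: str) -> dict[str, int]:
    gmap = tree.gate_map
    counts: dict[str, int] = {}

    def walk(node: str, mult: int) -> None:
        counts[node] = counts.get(node, 0) + mult
        gate = gmap.get(node)
        if gate is not None:
            for inp in gate.inputs:
                walk(inp, mult)

    walk(root, 1)
    return counts


def cut_set_bounds(cuts: CutSetCollection) -> tuple[float, float]:
    """(rare_event_sum, mcub) from a minimal cut-set collection."""
    probs = []
    for c in cuts:
        if c.probability is None:
            raise UnestimatedError(sorted(c.events))
        probs.append(c.probability)
    rare = float(sum(probs))
    mcub = 1.0 - math.prod(1.0 - p for p in probs)
    return rare, mcub


def top_probability_exact(
    tree: FaultTree,
    selector: str = "average",
    cuts: Optional[CutSetCollection] = None,
) -> TopEventResult:
    """Exact top-event probability plus rare-event and MCUB approximations.

    The rare-event sum may exceed 1; it is reported unclamped with
    ``rare_event_exceeds_one`` set so the approximation's breakdown stays
    visible.
    """
    tree.require_valid()
    probs = tree.leaf_probabilities(selector)
    exact, method = _exact(tree, probs, tree.top)
    if (
        cuts is None
        or cuts.truncation is not None
        or not _selector_matches(cuts, tree, selector)
    ):
        cuts = mocus_cut_sets(tree, selector=selector)
    rare, mcub = cut_set_bounds(cuts)
    return TopEventResult(
        exact=exact,
        rare_event_sum=rare,
        mcub=mcub,
        method=method,
        estimate_selector=selector,
        rare_event_exceeds_one=rare > 1.0,
        n_minimal_cut_sets=len(cuts),
    )


def _selector_matches(cuts: CutSetCollection, tree: FaultTree, selector: str) -> bool:
    if not cuts.cut_sets:
        return True
    c = cuts.cut_sets[0]
    if c.probability is None:
        return False
    expected = math.prod(tree.event(e).estimate.select(selector) for e in c.events)
    return math.isclose(c.probability, expected, rel_tol=1e-12, abs_tol=1e-15)


def all_gate_probabilities(tree: FaultTree, selector: str = "average") -> dict[str, float]:
    """Exact probability of the subtree rooted at every gate (top included)."""
    tree.require_valid()
    probs = tree.leaf_probabilities(selector)
    return {g.id: _exact(tree, dict(probs), g.id)[0] for g in tree.gates}


def brute_force_top(tree: FaultTree, selector: str = "average") -> float:
    """Independent oracle: sum of assignment weights over true-points (2^n)."""
    import itertools

    probs = tree.leaf_probabilities(selector)
    ids = sorted(probs)
    total = 0.0
    for bits in itertools.product([False, True], repeat=len(ids)):
        a = dict(zip(ids, bits))
        if structure_eval(tree, a):
            w = 1.0
            for eid in ids:
                w *= probs[eid] if a[eid] else 1.0 - probs[eid]
            total += w
    return total


def monte_carlo_top(
    tree: FaultTree,
    selector: str = "average",
    n: int = 10**6,
    seed: int = 0,
    chunk: int = 200_000,
) -> tuple[float, float]:
    """Monte Carlo estimate of the top-event probability.

    Draws ``n`` independent joint assignments (each event true with its
    selected probability), evaluates the structure function vectorised over
    gates in dependency order, and returns ``(estimate, half_width_95)``
    with the normal-approximation 95% half-width ``1.96*sqrt(p(1-p)/n)``.
    Reproducible for a fixed seed.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    tree.require_valid()
    probs = tree.leaf_probabilities(selector)
    event_ids = sorted(probs)
    p_vec = np.array([probs[e] for e in event_ids])
    order = _topological_gates(tree)
    rng = np.random.default_rng(seed)

    hits = 0
    remaining = n
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.random((m, len(event_ids))) < p_vec
        cols: dict[str, np.ndarray] = {e: draws[:, j] for j, e in enumerate(event_ids)}
        for gate in order:
            stacked = np.column_stack([cols[i] for i in gate.inputs])
            cols[gate.id] = stacked.all(axis=1) if gate.kind is GateKind.AND else stacked.any(axis=1)
        hits += int(cols[tree.top].sum())
        remaining -= m

    p_hat = hits / n
    half_width = 1.96 * math.sqrt(max(p_hat * (1.0 - p_hat), 0.0) / n)
    return p_hat, half_width


def _topological_gates(tree: FaultTree) -> list:
    """Gates ordered so every gate input appears before the gate itself."""
    gmap = tree.gate_map
    order: list = []
    state: dict[str, int] = {}

    def visit(gid: str) -> None:
        if state.get(gid) == 2:
            return
        state[gid] = 1
        for inp in gmap[gid].inputs:
            if inp in gmap and state.get(inp) != 2:
                visit(inp)
        state[gid] = 2
        order.append(gmap[gid])

    for g in tree.gates:
        visit(g.id)
    return order
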