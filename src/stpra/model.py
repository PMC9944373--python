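"""Fault-tree data model: events, gates, trees, validation and editing transforms.

A fault tree is a directed acyclic graph with a single top gate. Internal
nodes are AND/OR gates; leaves are *basic events* (risk factors), each
carrying a probability estimate aggregated from one or more literature or
expert sources. A basic event may feed several gates (a *repeated event*),
which is what makes exact probability computation non-trivial downstream.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence


class FaultTreeError(Exception):
    """Base class for all model errors."""


class DomainError(FaultTreeError, ValueError):
    """A value outside its mathematical domain (e.g. probability not in [0,1])."""


class StructuralError(FaultTreeError):
    """The tree violates a structural invariant (dangling id, cycle, ...)."""


class UnestimatedError(FaultTreeError):
    """An operation requiring probabilities met events without estimates."""

    def __init__(self, event_ids: Sequence[str]):
        self.event_ids = sorted(event_ids)
        super().__init__(
            "events without probability estimates: "
            + ", ".join(self.event_ids)
            + " (remove them with prune_unestimated)"
        )


class Provenance(str, enum.Enum):
    literature = "literature"
    expert = "expert"


class Theme(str, enum.Enum):
    """Risk-factor themes used when the seclusion-falls model was elicited."""

    patient_behavior = "patient_behavior"
    physical_condition = "physical_condition"
    medication = "medication"
    environment = "environment"
    prevention = "prevention"
    other = "other"


class GateKind(str, enum.Enum):
    AND = "AND"
    OR = "OR"


class AndPolicy(str, enum.Enum):
    """What exclude_events does when an excluded leaf feeds an AND gate."""

    forbid = "forbid"
    neutralize = "neutralize"


def _check_probability(value: float, what: str = "probability") -> float:
    if not isinstance(value, (int, float)) or isinstance(value, bool) or math.isnan(value):
        raise DomainError(f"{what} must be a number in [0, 1], got {value!r}")
    if not 0.0 <= value <= 1.0:
        raise DomainError(f"{what} must lie in [0, 1], got {value}")
    return float(value)


@dataclass(frozen=True)
class SourceEstimate:
    """A single elicited probability with its provenance."""

    value: float
    provenance: Provenance = Provenance.literature
    citation_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", _check_probability(self.value, "source value"))
        object.__setattr__(self, "provenance", Provenance(self.provenance))


@dataclass(frozen=True)
class ProbabilityEstimate:
    """Per-source values plus derived low/average/high point estimates.

    The derived values are never stored independently of the sources in
    serialized models; :func:`aggregate_estimates` is the single place the
    aggregation rule lives.
    """

    sources: tuple[SourceEstimate, ...] = ()
    low: Optional[float] = None
    average: Optional[float] = None
    high: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        derived = (self.low, self.average, self.high)
        if any(v is None for v in derived) != all(v is None for v in derived):
            raise DomainError("low/average/high must be all present or all absent")
        if self.low is not None:
            for name, v in zip(("low", "average", "high"), derived):
                _check_probability(v, name)
            if not (self.low <= self.average <= self.high + 1e-15):
                raise DomainError(
                    f"estimate ordering violated: low={self.low} average={self.average} high={self.high}"
                )

    @property
    def is_estimated(self) -> bool:
        return self.average is not None

    def select(self, selector: str) -> float:
        """Return the low/average/high point estimate by name."""
        if not self.is_estimated:
            raise UnestimatedError(["<unattached>"])
        if selector not in ("low", "average", "high"):
            raise DomainError(f"unknown estimate selector {selector!r}")
        return getattr(self, selector)


UNESTIMATED = ProbabilityEstimate()


def aggregate_estimates(sources: Iterable[SourceEstimate]) -> ProbabilityEstimate:
    """Derive low/average/high point estimates from elicited sources.

    Literature sources take priority: whenever any literature value exists,
    expert values are ignored (they were used in the study only where the
    literature was silent). With values ``V``:

    * ``average`` is ``mean(V)``;
    * ``low`` is the mean of ``V`` with one instance of its maximum removed
      (the estimate "without the highest reported probability value");
    * ``high`` is the mean with one instance of the minimum removed.

    A single value yields ``low == average == high``; no values yields an
    unestimated placeholder.
    """
    sources = tuple(sources)
    lit = [s.value for s in sources if s.provenance is Provenance.literature]
    exp = [s.value for s in sources if s.provenance is Provenance.expert]
    values = lit if lit else exp
    if not values:
        return ProbabilityEstimate(sources)
    if len(values) == 1:
        v = values[0]
        return ProbabilityEstimate(sources, low=v, average=v, high=v)
    average = sum(values) / len(values)
    without_max = sorted(values)[:-1]
    without_min = sorted(values)[1:]
    low = sum(without_max) / len(without_max)
    high = sum(without_min) / len(without_min)
    # Guard against float noise inverting the provable ordering.
    low = min(low, average)
    high = max(high, average)
    return ProbabilityEstimate(sources, low=low, average=average, high=high)


@dataclass(frozen=True)
class BasicEvent:
    """A risk factor: a leaf of the fault tree with an occurrence probability."""

    id: str
    label: str = ""
    theme: Theme = Theme.other
    estimate: ProbabilityEstimate = UNESTIMATED
    underdeveloped: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise DomainError("basic event id must be non-empty")
        object.__setattr__(self, "theme", Theme(self.theme))


@dataclass(frozen=True)
class Gate:
    id: str
    kind: GateKind
    inputs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise DomainError("gate id must be non-empty")
        object.__setattr__(self, "kind", GateKind(self.kind))
        object.__setattr__(self, "inputs", tuple(self.inputs))


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    subject_id: str

    def __post_init__(self) -> None:
        if self.severity not in ("error", "warning"):
            raise DomainError(f"unknown severity {self.severity!r}")


@dataclass(frozen=True)
class FaultTree:
    """An immutable fault-tree model.

    ``gates`` and ``events`` preserve declaration order (it is part of the
    serialization round-trip contract and drives deterministic cut-set
    expansion).
    """

    name: str
    top: str
    gates: tuple[Gate, ...]
    events: tuple[BasicEvent, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gates", tuple(self.gates))
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "metadata", dict(self.metadata))

    # -- lookups ------------------------------------------------------------
    @property
    def gate_map(self) -> dict[str, Gate]:
        return {g.id: g for g in self.gates}

    @property
    def event_map(self) -> dict[str, BasicEvent]:
        return {e.id: e for e in self.events}

    def gate(self, gate_id: str) -> Gate:
        try:
            return self.gate_map[gate_id]
        except KeyError:
            raise StructuralError(f"unknown gate id {gate_id!r}") from None

    def event(self, event_id: str) -> BasicEvent:
        try:
            return self.event_map[event_id]
        except KeyError:
            raise StructuralError(f"unknown event id {event_id!r}") from None

    def is_gate(self, node_id: str) -> bool:
        return node_id in self.gate_map

    def unestimated_events(self) -> list[str]:
        return sorted(e.id for e in self.events if not e.estimate.is_estimated)

    def reachable(self) -> set[str]:
        """Node ids reachable from the top gate."""
        gmap = self.gate_map
        seen: set[str] = set()
        stack = [self.top]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            g = gmap.get(node)
            if g is not None:
                stack.extend(g.inputs)
        return seen

    def leaf_probabilities(self, selector: str = "average") -> dict[str, float]:
        missing = self.unestimated_events()
        if missing:
            raise UnestimatedError(missing)
        return {e.id: e.estimate.select(selector) for e in self.events}

    def with_events(self, events: Iterable[BasicEvent]) -> "FaultTree":
        return replace(self, events=tuple(events))

    def require_valid(self) -> "FaultTree":
        issues = [i for i in validate(self) if i.severity == "error"]
        if issues:
            raise StructuralError(
                "invalid fault tree: " + "; ".join(f"[{i.code}] {i.message}" for i in issues)
            )
        return self


def validate(tree: FaultTree) -> list[ValidationIssue]:
    """Structural validation; returns deterministic, ordered issues.

    Errors (block analysis): duplicate ids, missing/dangling references,
    cycles, empty gates, repeated inputs within one gate. Warnings:
    single-input gates, nodes unreachable from the top.
    """
    issues: list[ValidationIssue] = []
    err = lambda code, msg, sid: issues.append(ValidationIssue("error", code, msg, sid))
    warn = lambda code, msg, sid: issues.append(ValidationIssue("warning", code, msg, sid))

    seen_ids: set[str] = set()
    for node_id in [g.id for g in tree.gates] + [e.id for e in tree.events]:
        if node_id in seen_ids:
            err("duplicate_id", f"id {node_id!r} declared more than once", node_id)
        seen_ids.add(node_id)

    gmap = {g.id: g for g in tree.gates}
    known = seen_ids
    if tree.top not in gmap:
        err("missing_top", f"top gate {tree.top!r} is not a declared gate", tree.top)

    for g in tree.gates:
        if len(g.inputs) == 0:
            err("empty_gate", f"gate {g.id!r} has no inputs", g.id)
        elif len(g.inputs) == 1:
            warn("single_input", f"gate {g.id!r} has a single input", g.id)
        seen_inputs: set[str] = set()
        for inp in g.inputs:
            if inp in seen_inputs:
                err("duplicate_input", f"gate {g.id!r} lists input {inp!r} twice", g.id)
            seen_inputs.add(inp)
            if inp not in known:
                err("dangling", f"gate {g.id!r} references undeclared id {inp!r}", inp)

    # Cycle detection over the gate graph (iterative colouring DFS).
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {gid: WHITE for gid in gmap}
    for start in gmap:
        if colour[start] != WHITE:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        colour[start] = GREY
        while stack:
            node, idx = stack[-1]
            children = [c for c in gmap[node].inputs if c in gmap]
            if idx < len(children):
                stack[-1] = (node, idx + 1)
                child = children[idx]
                if colour[child] == GREY:
                    err("cycle", f"gate {child!r} participates in a cycle", child)
                elif colour[child] == WHITE:
                    colour[child] = GREY
                    stack.append((child, 0))
            else:
                colour[node] = BLACK
                stack.pop()

    has_cycle = any(i.code == "cycle" for i in issues)
    if tree.top in gmap and not has_cycle:
        reachable = tree.reachable()
        for node_id in sorted(known - reachable):
            warn("unreachable", f"node {node_id!r} is not reachable from the top gate", node_id)

    issues.sort(key=lambda i: (i.subject_id, i.code, i.severity, i.message))
    return issues


def prune_unestimated(tree: FaultTree) -> tuple[FaultTree, list[str]]:
    """Remove every basic event lacking a probability estimate.

    Removal follows :func:`exclude_events` with the ``forbid`` AND-policy:
    an unestimated conjunct cannot simply be dropped from an AND gate, since
    that would silently weaken the failure condition.
    """
    tree.require_valid()
    removed = tree.unestimated_events()
    if not removed:
        return tree, []
    pruned = exclude_events(tree, set(removed), AndPolicy.forbid)
    return pruned, removed


def exclude_events(
    tree: FaultTree, ids: Iterable[str], and_policy: AndPolicy | str = AndPolicy.forbid
) -> FaultTree:
    """Remove risk factors from the model (scenario/sensitivity transform).

    Each named leaf is deleted from every OR parent; an OR gate emptied this
    way disappears from its own parents, recursively. Under ``forbid``,
    touching an AND gate's input raises. Under ``neutralize`` an excluded
    leaf that feeds an AND gate is kept there with probability pinned to 1
    (a logically always-true conjunct) while still being deleted from OR
    parents. A cascade that would delete a *gate* input of an AND gate
    raises under both policies.
    """
    and_policy = AndPolicy(and_policy)
    ids = set(ids)
    emap = tree.event_map
    unknown = ids - set(emap)
    if unknown:
        raise StructuralError(f"cannot exclude unknown event ids: {sorted(unknown)}")

    gmap = {g.id: g for g in tree.gates}
    neutralized: set[str] = set()

    def parents_of(node_id: str) -> list[Gate]:
        return [g for g in gmap.values() if node_id in g.inputs]

    # First pass: leaf deletions.
    for eid in sorted(ids):
        for parent in parents_of(eid):
            if parent.kind is GateKind.AND:
                if and_policy is AndPolicy.forbid:
                    raise StructuralError(
                        f"excluding event {eid!r} would remove an input of AND gate "
                        f"{parent.id!r} (policy=forbid)"
                    )
                neutralized.add(eid)
            else:
                g = gmap[parent.id]
                gmap[parent.id] = replace(g, inputs=tuple(i for i in g.inputs if i != eid))

    # Cascade: delete emptied OR gates from their parents until stable.
    while True:
        empty = [g for g in gmap.values() if not g.inputs and g.kind is GateKind.OR]
        dead_and = [g for g in gmap.values() if not g.inputs and g.kind is GateKind.AND]
        if dead_and:
            raise StructuralError(
                f"exclusion emptied AND gate {dead_and[0].id!r}"
            )
        if not empty:
            break
        for victim in empty:
            if victim.id == tree.top:
                raise StructuralError("empty model: exclusion eliminated the top gate")
            for parent in parents_of(victim.id):
                if parent.kind is GateKind.AND:
                    raise StructuralError(
                        f"exclusion cascade would remove emptied gate {victim.id!r} "
                        f"from AND gate {parent.id!r}"
                    )
                g = gmap[parent.id]
                gmap[parent.id] = replace(
                    g, inputs=tuple(i for i in g.inputs if i != victim.id)
                )
            del gmap[victim.id]

    kept_gates = tuple(gmap[g.id] for g in tree.gates if g.id in gmap)
    referenced: set[str] = set()
    for g in kept_gates:
        referenced.update(g.inputs)

    new_events = []
    for e in tree.events:
        if e.id in ids and e.id not in neutralized:
            continue
        if e.id not in referenced:
            continue
        if e.id in neutralized:
            pinned = ProbabilityEstimate(
                sources=(SourceEstimate(1.0, Provenance.expert, "neutralized exclusion"),),
                low=1.0, average=1.0, high=1.0,
            )
            e = replace(e, estimate=pinned)
        new_events.append(e)

    result = FaultTree(
        name=tree.name,
        top=tree.top,
        gates=kept_gates,
        events=tuple(new_events),
        metadata=dict(tree.metadata),
    )
    return result.require_valid()
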