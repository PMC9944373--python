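"""Minimal cut sets — the model's "critical paths".

A cut set is a set of risk factors whose joint occurrence forces the top
event; a *minimal* cut set contains no smaller cut set. Enumeration is
top-down MOCUS expansion: a work list of rows starts at ``{top}``; an OR
gate in a row branches the row into one copy per input, an AND gate
extends the row with all inputs; rows are sets, so a repeated event
collapses by idempotence during expansion. Absorption (superset removal)
runs as a final minimization pass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import FaultTree, GateKind, FaultTreeError, StructuralError


class ResourceLimitError(FaultTreeError):
    """Cut-set expansion exceeded the configured row cap."""


@dataclass(frozen=True)
class CutSet:
    events: frozenset[str]
    probability: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.events:
            raise StructuralError("a cut set must be non-empty")
        object.__setattr__(self, "events", frozenset(self.events))

    @property
    def order(self) -> int:
        return len(self.events)

    def sorted_events(self) -> tuple[str, ...]:
        return tuple(sorted(self.events))


@dataclass(frozen=True)
class CutSetCollection:
    cut_sets: tuple[CutSet, ...]
    truncation: Optional[int] = None
    complete: bool = True

    def __len__(self) -> int:
        return len(self.cut_sets)

    def __iter__(self):
        return iter(self.cut_sets)

    def sets(self) -> list[frozenset[str]]:
        return [c.events for c in self.cut_sets]

    def containing(self, event_id: str) -> list[CutSet]:
        return [c for c in self.cut_sets if event_id in c.events]


def minimize_cut_sets(raw: Iterable[Iterable[str]]) -> list[frozenset[str]]:
    """Remove duplicates and absorbed (superset) sets; idempotent.

    Output is sorted by (size, member ids) for determinism; probability-based
    ordering happens in :func:`mocus_cut_sets` where probabilities exist.
    """
    unique = sorted({frozenset(s) for s in raw}, key=lambda s: (len(s), tuple(sorted(s))))
    kept: list[frozenset[str]] = []
    for cand in unique:  # ascending size: any absorber of cand is already kept
        if not any(k <= cand for k in kept):
            kept.append(cand)
    return kept


def _expand(tree: FaultTree, cap: int) -> list[frozenset[str]]:
    gmap = tree.gate_map
    rows: list[frozenset[str]] = [frozenset([tree.top])]
    done: list[frozenset[str]] = []
    while rows:
        row = rows.pop()
        gate_ids = sorted(n for n in row if n in gmap)
        if not gate_ids:
            done.append(row)
            continue
        gid = gate_ids[0]
        gate = gmap[gid]
        rest = row - {gid}
        if gate.kind is GateKind.AND:
            rows.append(rest | set(gate.inputs))
        else:
            # declared input order, reversed so the stack pops in order
            for inp in reversed(gate.inputs):
                rows.append(rest | {inp})
        if len(rows) + len(done) > cap:
            raise ResourceLimitError(
                f"cut-set expansion exceeded {cap} rows; re-run with a max_order "
                "truncation or raise the cap"
            )
    return done


def mocus_cut_sets(
    tree: FaultTree,
    max_order: Optional[int] = None,
    selector: str = "average",
    cap: int = 10**6,
) -> CutSetCollection:
    """Enumerate the minimal cut sets of a valid tree.

    ``max_order`` truncates *after* minimization (pre-truncation could delete
    the absorber of a low-order set and leave a non-minimal survivor).
    Probabilities are products of member point estimates under ``selector``
    (left absent when any member is unestimated). Ordering: descending
    probability, ties by lexicographic member ids — byte-stable across runs.
    """
    tree.require_valid()
    minimal = minimize_cut_sets(_expand(tree, cap))
    complete = True
    truncation = None
    if max_order is not None:
        truncation = max_order
        before = len(minimal)
        minimal = [s for s in minimal if len(s) <= max_order]
        complete = len(minimal) == before

    emap = tree.event_map
    def prob(s: frozenset[str]) -> Optional[float]:
        p = 1.0
        for eid in s:
            est = emap[eid].estimate
            if not est.is_estimated:
                return None
            p *= est.select(selector)
        return p

    cut_sets = [CutSet(s, prob(s)) for s in minimal]
    cut_sets.sort(key=lambda c: (-(c.probability if c.probability is not None else -1.0),
                                 c.sorted_events()))
    return CutSetCollection(tuple(cut_sets), truncation=truncation, complete=complete)


def is_cut_set(tree: FaultTree, events: Iterable[str]) -> bool:
    """True iff setting exactly these events true forces the top event."""
    from .probability import structure_eval  # local import avoids a cycle

    events = set(events)
    known = set(tree.event_map)
    unknown = events - known
    if unknown:
        raise StructuralError(f"unknown event ids: {sorted(unknown)}")
    assignment = {eid: (eid in events) for eid in known}
    return structure_eval(tree, assignment)


def is_minimal(tree: FaultTree, events: Iterable[str]) -> bool:
    """True iff the set is a cut set and no proper subset is one."""
    events = set(events)
    if not is_cut_set(tree, events):
        return False
    for drop in events:
        if is_cut_set(tree, events - {drop}):
            return False
    return True


def brute_force_cut_sets(tree: FaultTree) -> list[frozenset[str]]:
    """Independent oracle: minimal true-points of the structure function.

    Enumerates all 2^n assignments; intended for trees with few events in
    tests and cross-checks, never as the production path.
    """
    from .probability import structure_eval

    ids = sorted(tree.event_map)
    true_points = []
    for bits in itertools.product([False, True], repeat=len(ids)):
        a = dict(zip(ids, bits))
        if structure_eval(tree, a):
            true_points.append(frozenset(e for e, b in a.items() if b))
    return minimize_cut_sets(true_points)
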