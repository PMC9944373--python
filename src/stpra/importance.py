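"""Importance measures and sensitivity analyses.

Three standard coherent-system importance measures are co-reported for each
risk factor ``e`` with probability ``p_e`` and top-event probability ``Q``:

* Birnbaum: ``B_e = Q(p_e = 1) - Q(p_e = 0)`` — the structure-polynomial
  partial derivative with respect to ``p_e``.
* Criticality importance: ``B_e * p_e / Q`` — the probability that the top
  event occurs *and* a change of state of ``e`` was decisive, given the top
  event occurred. This is the definition commercial PRA tools report under
  the name "criticality".
* Fussell–Vesely: ``P(union of minimal cut sets containing e) / Q`` — the
  probability the adverse outcome came through a failure path involving
  ``e``.

Sensitivity analyses follow the elicitation design: bound analysis re-runs
the model under the low/average/high source-aggregation selectors, and
leave-out analysis removes named risk factors and reports the change in
top-event probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cutsets import CutSetCollection, minimize_cut_sets, mocus_cut_sets
from .model import AndPolicy, FaultTree, FaultTreeError, exclude_events
from .probability import top_probability_exact, _exact

MEASURES = ("criticality", "fussell_vesely", "birnbaum")


class DegenerateModelError(FaultTreeError):
    """Importance is undefined when the top-event probability is zero."""


@dataclass(frozen=True)
class ImportanceRecord:
    event_id: str
    probability: float
    birnbaum: float
    criticality: float
    fussell_vesely: float
    underdeveloped: bool = False


@dataclass(frozen=True)
class SensitivityRow:
    label: str
    detail: str
    top_probability: float
    delta_vs_baseline: float


@dataclass(frozen=True)
class SensitivityTable:
    baseline_label: str
    rows: tuple[SensitivityRow, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "scenario": r.label,
                    "detail": r.detail,
                    "top_probability": r.top_probability,
                    "delta_vs_baseline": r.delta_vs_baseline,
                }
                for r in self.rows
            ]
        )


def monotone_dnf_probability(
    family: Sequence[frozenset[str]], probs: dict[str, float]
) -> float:
    """Exact probability that at least one set of a monotone DNF occurs.

    Shannon decomposition on the most frequent member with absorption after
    every pivot and memoization on the reduced family. Product-structured
    families (such as the cut sets through one event of an AND-of-ORs tree)
    collapse quickly; the generic worst case is exponential, as exact
    monotone-DNF probability must be.
    """
    memo: dict[frozenset[frozenset[str]], float] = {}

    def solve(sets: frozenset[frozenset[str]]) -> float:
        if not sets:
            return 0.0
        if frozenset() in sets:
            return 1.0
        if len(sets) == 1:
            p = 1.0
            for e in next(iter(sets)):
                p *= probs[e]
            return p
        cached = memo.get(sets)
        if cached is not None:
            return cached
        counts: dict[str, int] = {}
        for s in sets:
            for e in s:
                counts[e] = counts.get(e, 0) + 1
        pivot = min(counts, key=lambda e: (-counts[e], e))
        p = probs[pivot]
        # pivot true: drop it from its sets, then absorb supersets
        reduced = [s - {pivot} if pivot in s else s for s in sets]
        true_branch = frozenset(minimize_cut_sets(reduced))
        false_branch = frozenset(s for s in sets if pivot not in s)
        value = p * solve(true_branch) + (1.0 - p) * solve(false_branch)
        memo[sets] = value
        return value

    return solve(frozenset(minimize_cut_sets(family)))


def _cut_set_union_probability(
    tree: FaultTree, cut_sets: Sequence[frozenset[str]], selector: str
) -> float:
    """Exact probability that at least one of the given cut sets occurs."""
    if not cut_sets:
        return 0.0
    probs = tree.leaf_probabilities(selector)
    return monotone_dnf_probability(cut_sets, probs)


def importance_all(
    tree: FaultTree,
    selector: str = "average",
    cuts: Optional[CutSetCollection] = None,
) -> list[ImportanceRecord]:
    """One importance record per basic event, in event-id order."""
    tree.require_valid()
    probs = tree.leaf_probabilities(selector)
    q_top = _exact(tree, dict(probs), tree.top)[0]
    if q_top <= 0.0:
        raise DegenerateModelError("degenerate model: top-event probability is zero")
    if cuts is None:
        cuts = mocus_cut_sets(tree, selector=selector)

    records = []
    for eid in sorted(probs):
        p_e = probs[eid]
        q_hi = _exact(tree, {**probs, eid: 1.0}, tree.top)[0]
        q_lo = _exact(tree, {**probs, eid: 0.0}, tree.top)[0]
        birnbaum = q_hi - q_lo
        criticality = birnbaum * p_e / q_top
        fv_sets = [c.events for c in cuts.containing(eid)]
        fv = _cut_set_union_probability(tree, fv_sets, selector) / q_top
        records.append(
            ImportanceRecord(
                event_id=eid,
                probability=p_e,
                birnbaum=birnbaum,
                criticality=criticality,
                fussell_vesely=fv,
                underdeveloped=tree.event(eid).underdeveloped,
            )
        )
    return records


def rank_events(
    records: Iterable[ImportanceRecord], measure: str = "criticality"
) -> list[ImportanceRecord]:
    """Descending by the chosen measure; ties broken by event id (stable)."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    return sorted(records, key=lambda r: (-getattr(r, measure), r.event_id))


def importance_table(records: Iterable[ImportanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event": r.event_id,
                "probability": r.probability,
                "birnbaum": r.birnbaum,
                "criticality": r.criticality,
                "fussell_vesely": r.fussell_vesely,
                "underdeveloped": r.underdeveloped,
            }
            for r in records
        ]
    )


def bound_analysis(tree: FaultTree) -> SensitivityTable:
    """Top-event probability under the low / average / high selectors.

    Coherence guarantees the three rows are monotone non-decreasing.
    """
    baseline = top_probability_exact(tree, "average").exact
    rows = []
    for selector in ("low", "average", "high"):
        q = top_probability_exact(tree, selector).exact
        rows.append(
            SensitivityRow(
                label=selector,
                detail=f"selector={selector}",
                top_probability=q,
                delta_vs_baseline=q - baseline,
            )
        )
    return SensitivityTable(baseline_label="average", rows=tuple(rows))


def leave_out_analysis(
    tree: FaultTree,
    exclusion_sets: Sequence[tuple[str, Iterable[str]]],
    selector: str = "average",
    and_policy: AndPolicy | str = AndPolicy.forbid,
) -> SensitivityTable:
    """Top-event probability with named risk-factor groups removed.

    Mirrors the elicitation-stage check of running the model with and
    without contested risk factors (e.g. advanced age, history of medical
    problems) before deciding whether to keep them.
    """
    baseline = top_probability_exact(tree, selector).exact
    rows = [
        SensitivityRow(
            label="baseline",
            detail="no exclusions",
            top_probability=baseline,
            delta_vs_baseline=0.0,
        )
    ]
    for label, ids in exclusion_sets:
        ids = sorted(set(ids))
        if not ids:
            q = baseline
        else:
            reduced = exclude_events(tree, ids, and_policy)
            q = top_probability_exact(reduced, selector).exact
        rows.append(
            SensitivityRow(
                label=label,
                detail="excluded: " + (", ".join(ids) if ids else "none"),
                top_probability=q,
                delta_vs_baseline=q - baseline,
            )
        )
    return SensitivityTable(baseline_label="baseline", rows=tuple(rows))
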