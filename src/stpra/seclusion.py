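"""The packaged seclusion-falls model and the report builder.

The shipped fixture reconstructs the *critical-path architecture* of a
patient fall in a psychiatric seclusion room: the top AND requires a
disorder, a mechanism of fall, a reason for the fall, and a prevention
failure, where prevention fails only when both the fall-risk assessment
and the fall-prevention intervention fail (the second AND). Leaf
probabilities are an illustrative overlay (synthetic, plausible
magnitudes), kept in a separate data file so structure and numbers are
independently versioned. The full elicited model (88 risk factors, 22 OR
gates) lives in an external open-data deposit; ``load_deposited_model``
is the adapter seam for it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .cutsets import mocus_cut_sets
from .importance import bound_analysis, importance_all, rank_events
from .io import ParseError, parse_model, serialize_model, tree_from_dict
from .model import FaultTree, StructuralError
from .probability import all_gate_probabilities, monte_carlo_top, top_probability_exact

ZENODO_DOI = "10.5281/zenodo.7276312"


def _read_data(name: str) -> dict:
    with resources.files("stpra.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def load_seclusion_skeleton(with_probabilities: bool = True) -> FaultTree:
    """Load the packaged seclusion-falls reconstruction.

    With ``with_probabilities`` the illustrative source overlay is applied
    and aggregated; without it every leaf is unestimated (pure structure).
    """
    doc = _read_data("seclusion_skeleton.json")
    if with_probabilities:
        overlay = _read_data("seclusion_probabilities.json")["sources"]
        for event in doc["events"]:
            event["sources"] = overlay.get(event["id"], [])
    return tree_from_dict(doc)


def load_deposited_model(path: str) -> FaultTree:
    """Adapter for the open-data deposit of the full elicited model.

    Accepts any file already in a supported native format; an unrecognized
    schema raises with a content fingerprint so a dedicated adapter can be
    written against the actual deposit.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    except FileNotFoundError:
        raise FileNotFoundError(
            f"deposited model not found at {path!r}; download the open-data "
            f"record (doi.{ZENODO_DOI}) and pass its local path"
        ) from None
    for fmt in ("json", "yaml", "openpsa_xml"):
        try:
            return parse_model(text, fmt)
        except (ParseError, StructuralError):
            continue
    fingerprint = hashlib.sha256(text.encode()).hexdigest()[:16]
    raise ParseError(
        f"adapter required: file {path!r} (sha256 {fingerprint}...) does not "
        "match any supported schema; a bespoke adapter for the deposit "
        f"(doi.{ZENODO_DOI}) is needed"
    )


@dataclass(frozen=True)
class AnalysisReport:
    """Assembled engine outputs for one model; deterministic given inputs."""

    payload: dict

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=2, sort_keys=True) + "\n"

    def to_text(self) -> str:
        p = self.payload
        lines = [
            f"Fault-tree analysis report — {p['model']['name']}",
            f"model sha256: {p['model']['sha256'][:16]}...",
            f"provenance: {p['provenance']}",
            "",
            "Top-event probability (exact / MCUB / rare-event sum):",
        ]
        for sel in ("low", "average", "high"):
            r = p["top_event"][sel]
            lines.append(
                f"  {sel:>7}: {r['exact']:.6f} / {r['mcub']:.6f} / {r['rare_event_sum']:.6f}"
            )
        if p.get("monte_carlo"):
            mc = p["monte_carlo"]
            lines.append(
                f"  Monte Carlo ({mc['n']} draws, seed {mc['seed']}): "
                f"{mc['estimate']:.6f} +/- {mc['half_width_95']:.6f}"
            )
        lines.append("")
        lines.append(f"Minimal cut sets: {p['cut_sets']['count']} (top {len(p['cut_sets']['top'])}):")
        for c in p["cut_sets"]["top"]:
            lines.append(f"  {c['probability']:.6f}  {{{', '.join(c['events'])}}}")
        lines.append("")
        lines.append("Most important risk factors (by criticality):")
        for r in p["importance"][:10]:
            lines.append(
                f"  {r['criticality']:.6f}  {r['event']}"
                + ("  [underdeveloped]" if r["underdeveloped"] else "")
            )
        if p["underdeveloped_events"]:
            lines.append("")
            lines.append("Underdeveloped events: " + ", ".join(p["underdeveloped_events"]))
        return "\n".join(lines) + "\n"


def build_report(
    tree: FaultTree,
    top_k: int = 10,
    selector: str = "average",
    mc_samples: Optional[int] = None,
    seed: int = 0,
) -> AnalysisReport:
    """Run the full pipeline and assemble a deterministic report.

    Every number is re-derived from a fresh engine run on the given tree;
    the report caches nothing.
    """
    tree.require_valid()
    serialized = serialize_model(tree, "json")
    model_hash = hashlib.sha256(serialized.encode()).hexdigest()

    cuts = mocus_cut_sets(tree, selector=selector)
    top_event = {}
    for sel in ("low", "average", "high"):
        res = top_probability_exact(tree, sel)
        top_event[sel] = {
            "exact": res.exact,
            "mcub": res.mcub,
            "rare_event_sum": res.rare_event_sum,
            "method": res.method,
        }
    records = rank_events(importance_all(tree, selector, cuts=cuts), "criticality")
    bounds = bound_analysis(tree)

    provenance = "deposited model"
    if tree.metadata.get("illustrative"):
        provenance = "reconstruction — illustrative probabilities"
    elif tree.metadata.get("synthetic"):
        provenance = "synthetic model"

    payload = {
        "model": {"name": tree.name, "sha256": model_hash,
                  "n_events": len(tree.events), "n_gates": len(tree.gates)},
        "provenance": provenance,
        "selector": selector,
        "top_event": top_event,
        "gate_probabilities": all_gate_probabilities(tree, selector),
        "cut_sets": {
            "count": len(cuts),
            "complete": cuts.complete,
            "top": [
                {"events": list(c.sorted_events()), "probability": c.probability}
                for c in cuts.cut_sets[:top_k]
            ],
        },
        "importance": [
            {
                "event": r.event_id,
                "probability": r.probability,
                "birnbaum": r.birnbaum,
                "criticality": r.criticality,
                "fussell_vesely": r.fussell_vesely,
                "underdeveloped": r.underdeveloped,
            }
            for r in records
        ],
        "sensitivity_bounds": [
            {
                "scenario": row.label,
                "top_probability": row.top_probability,
                "delta_vs_baseline": row.delta_vs_baseline,
            }
            for row in bounds.rows
        ],
        "underdeveloped_events": sorted(e.id for e in tree.events if e.underdeveloped),
    }
    if mc_samples:
        est, hw = monte_carlo_top(tree, selector, n=mc_samples, seed=seed)
        payload["monte_carlo"] = {
            "estimate": est, "half_width_95": hw, "n": mc_samples, "seed": seed,
        }
    else:
        payload["monte_carlo"] = None
    return AnalysisReport(payload)
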