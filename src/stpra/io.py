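"""Serialization of fault-tree models.

Native formats are a JSON dialect and its 1:1 YAML surface. Top-level keys:
``name``, ``top``, ``gates`` (list of ``{id, kind, inputs}``), ``events``
(list of ``{id, label, theme, underdeveloped, sources}``) and optional
``metadata``. Derived low/average/high estimates are *recomputed on load*
from the sources — the file never carries them, so the aggregation rule has
a single home (:func:`stpra.model.aggregate_estimates`).

An Open-PSA Model Exchange Format surface is provided for interoperability
with other PRA tools. It is lossy: each basic event carries one point
probability (the average estimate); themes, provenance and multi-source
detail do not survive the trip.
"""

from __future__ import annotations

import json
from typing import Iterable

import yaml
from lxml import etree

from .model import (
    BasicEvent,
    FaultTree,
    Gate,
    GateKind,
    ProbabilityEstimate,
    Provenance,
    SourceEstimate,
    StructuralError,
    Theme,
    aggregate_estimates,
    validate,
)

FORMATS = ("json", "yaml", "openpsa_xml")


class ParseError(StructuralError):
    """The stream is not a well-formed model in the named format."""


def tree_to_dict(tree: FaultTree) -> dict:
    """Plain-dict form of a tree (the JSON dialect, before encoding)."""
    d: dict = {
        "name": tree.name,
        "top": tree.top,
        "gates": [
            {"id": g.id, "kind": g.kind.value, "inputs": list(g.inputs)} for g in tree.gates
        ],
        "events": [
            {
                "id": e.id,
                "label": e.label,
                "theme": e.theme.value,
                "underdeveloped": e.underdeveloped,
                "sources": [
                    {
                        "value": s.value,
                        "provenance": s.provenance.value,
                        "citation_label": s.citation_label,
                    }
                    for s in e.estimate.sources
                ],
            }
            for e in tree.events
        ],
    }
    if tree.metadata:
        d["metadata"] = dict(tree.metadata)
    return d


def tree_from_dict(d: dict) -> FaultTree:
    try:
        gates = tuple(
            Gate(id=g["id"], kind=GateKind(g["kind"]), inputs=tuple(g["inputs"]))
            for g in d.get("gates", [])
        )
        events = tuple(
            BasicEvent(
                id=e["id"],
                label=e.get("label", ""),
                theme=Theme(e.get("theme", "other")),
                underdeveloped=bool(e.get("underdeveloped", False)),
                estimate=aggregate_estimates(
                    SourceEstimate(
                        value=s["value"],
                        provenance=Provenance(s.get("provenance", "literature")),
                        citation_label=s.get("citation_label", ""),
                    )
                    for s in e.get("sources", [])
                ),
            )
            for e in d.get("events", [])
        )
        tree = FaultTree(
            name=d.get("name", ""),
            top=d["top"],
            gates=gates,
            events=events,
            metadata=d.get("metadata", {}),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed model document: {exc}") from exc
    _raise_on_structural_errors(tree)
    return tree


def _raise_on_structural_errors(tree: FaultTree) -> None:
    errors = [i for i in validate(tree) if i.severity == "error"]
    if errors:
        raise StructuralError(
            "; ".join(f"[{i.code}] {i.message}" for i in errors)
        )


def parse_model(stream: str, format: str = "json") -> FaultTree:
    """Parse a fault-tree model from text in the named format."""
    if format == "json":
        try:
            d = json.loads(stream)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON at line {exc.lineno}: {exc.msg}") from exc
        return tree_from_dict(d)
    if format == "yaml":
        try:
            d = yaml.safe_load(stream)
        except yaml.YAMLError as exc:
            raise ParseError(f"invalid YAML: {exc}") from exc
        if not isinstance(d, dict):
            raise ParseError("YAML document is not a mapping")
        return tree_from_dict(d)
    if format == "openpsa_xml":
        return _parse_openpsa(stream)
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def serialize_model(tree: FaultTree, format: str = "json") -> str:
    """Serialize a valid tree; probabilities keep full precision in the native formats."""
    _raise_on_structural_errors(tree)
    if format == "json":
        return json.dumps(tree_to_dict(tree), indent=2, sort_keys=False) + "\n"
    if format == "yaml":
        return yaml.safe_dump(tree_to_dict(tree), sort_keys=False)
    if format == "openpsa_xml":
        return _serialize_openpsa(tree)
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


# ---------------------------------------------------------------------------
# Open-PSA MEF (lossy: point probability = average)
# ---------------------------------------------------------------------------

def _serialize_openpsa(tree: FaultTree) -> str:
    root = etree.Element("opsa-mef")
    ft = etree.SubElement(root, "define-fault-tree", name=tree.name or "fault-tree")
    for g in tree.gates:
        dg = etree.SubElement(ft, "define-gate", name=g.id)
        op = etree.SubElement(dg, g.kind.value.lower())
        gate_ids = {gg.id for gg in tree.gates}
        for inp in g.inputs:
            if inp in gate_ids:
                etree.SubElement(op, "gate", name=inp)
            else:
                etree.SubElement(op, "basic-event", name=inp)
    md = etree.SubElement(root, "model-data")
    for e in tree.events:
        dbe = etree.SubElement(md, "define-basic-event", name=e.id)
        if e.estimate.is_estimated:
            etree.SubElement(dbe, "float", value=repr(e.estimate.average))
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def _parse_openpsa(stream: str) -> FaultTree:
    try:
        root = etree.fromstring(stream.encode())
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"invalid XML: {exc}") from exc
    if root.tag != "opsa-mef":
        raise ParseError(f"expected <opsa-mef> document, got <{root.tag}>")
    ft = root.find("define-fault-tree")
    if ft is None:
        raise ParseError("missing <define-fault-tree> element")

    gates: list[Gate] = []
    for dg in ft.findall("define-gate"):
        ops = [child for child in dg if child.tag in ("and", "or")]
        if len(ops) != 1:
            raise ParseError(f"gate {dg.get('name')!r} must contain exactly one <and>/<or>")
        op = ops[0]
        inputs = tuple(
            child.get("name")
            for child in op
            if child.tag in ("gate", "basic-event")
        )
        gates.append(Gate(id=dg.get("name"), kind=GateKind(op.tag.upper()), inputs=inputs))

    events: list[BasicEvent] = []
    md = root.find("model-data")
    if md is not None:
        for dbe in md.findall("define-basic-event"):
            flt = dbe.find("float")
            if flt is not None:
                est = aggregate_estimates(
                    [SourceEstimate(float(flt.get("value")), Provenance.literature, "openpsa")]
                )
            else:
                est = ProbabilityEstimate()
            events.append(BasicEvent(id=dbe.get("name"), estimate=est))

    if not gates:
        raise ParseError("fault tree defines no gates")
    referenced = {inp for g in gates for inp in g.inputs}
    top_candidates = [g.id for g in gates if g.id not in referenced]
    top = top_candidates[0] if top_candidates else gates[0].id
    tree = FaultTree(
        name=ft.get("name", ""),
        top=top,
        gates=tuple(gates),
        events=tuple(events),
    )
    _raise_on_structural_errors(tree)
    return tree


def load_model(path: str) -> FaultTree:
    """Load a model file, inferring the format from its extension."""
    fmt = "json"
    if path.endswith((".yaml", ".yml")):
        fmt = "yaml"
    elif path.endswith(".xml"):
        fmt = "openpsa_xml"
    with open(path, "r", encoding="utf-8") as fh:
        return parse_model(fh.read(), fmt)
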