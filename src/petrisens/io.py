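"""Reading and writing Petri nets.

Three formats are supported:

* **PNML** (ISO/IEC 15909-2 core model) — the interchange format of record;
  read and write, exact round-trip of places, transitions, arcs, weights and
  marking.
* **Snoopy ``.spped``** — read-only, best effort, covering the discrete
  place/transition dialect.  Graphics are ignored; logical places (multiple
  place nodes sharing one display name, a drawing convenience for large
  nets) are merged into a single place with their arcs rewired.
* **CSV arc list** — a minimal dialect with header ``source,target[,weight]``
  where ids starting with ``p``/``P`` are places and ``t``/``T`` transitions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO

from lxml import etree

from .net import NetStructureError, PetriNet

__all__ = [
    "FormatError",
    "NetDocument",
    "read_pnml",
    "write_pnml",
    "read_spped",
    "read_csv_arclist",
    "read_net",
]

PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"


class FormatError(ValueError):
    """Raised on malformed or unsupported input files."""


@dataclass
class NetDocument:
    net: PetriNet
    format: str                       # "pnml" | "spped" | "csv"
    annotations: dict[str, str] = field(default_factory=dict)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse_xml(stream: IO[bytes] | IO[str] | str) -> etree._Element:
    try:
        if isinstance(stream, str):
            return etree.parse(stream).getroot()
        data = stream.read()
        if isinstance(data, str):
            data = data.encode("utf-8")
        return etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed XML: {exc}") from exc


# ---------------------------------------------------------------------------
# PNML

def read_pnml(stream: IO[bytes] | IO[str] | str) -> NetDocument:
    """Read a PNML core-model document (namespace-agnostic).

    Arcs without an inscription default to weight 1; places without an
    initialMarking default to 0 tokens.
    """
    root = _parse_xml(stream)
    net = PetriNet()
    pages = [el for el in root.iter() if _local(el.tag) in ("net", "page")]
    if not pages:
        raise FormatError("no <net> element found")
    net.net_id = pages[0].get("id", "net")
    arcs: list[tuple[str, str, int, str]] = []
    for el in root.iter():
        tag = _local(el.tag)
        if tag == "place":
            pid = el.get("id")
            if pid is None:
                raise FormatError("place without id")
            net.add_place(pid, _pnml_text(el, "name") or pid,
                          int(_pnml_text(el, "initialMarking") or 0))
        elif tag == "transition":
            tid = el.get("id")
            if tid is None:
                raise FormatError("transition without id")
            net.add_transition(tid, _pnml_text(el, "name") or tid)
    for el in root.iter():
        if _local(el.tag) == "arc":
            src, tgt = el.get("source"), el.get("target")
            if src is None or tgt is None:
                raise FormatError(f"arc {el.get('id')!r} missing source/target")
            weight = int(_pnml_text(el, "inscription") or 1)
            arcs.append((src, tgt, weight, el.get("id", "")))
    for src, tgt, weight, aid in arcs:
        try:
            net.add_arc(src, tgt, weight)
        except NetStructureError as exc:
            raise FormatError(f"arc {aid!r}: {exc}") from exc
    return NetDocument(net, "pnml")


def _pnml_text(el: etree._Element, child_tag: str) -> str | None:
    for child in el:
        if _local(child.tag) == child_tag:
            for sub in child:
                if _local(sub.tag) == "text":
                    return sub.text
            return child.text
    return None


def write_pnml(doc: NetDocument, stream: IO[bytes] | str) -> None:
    """Write a schema-valid PNML core document with deterministic element
    order: places, then transitions, then arcs, each sorted by id."""
    net = doc.net
    nsmap = {None: PNML_NS}
    root = etree.Element(f"{{{PNML_NS}}}pnml", nsmap=nsmap)
    net_el = etree.SubElement(root, f"{{{PNML_NS}}}net", id=net.net_id,
                              type="http://www.pnml.org/version-2009/grammar/ptnet")
    page = etree.SubElement(net_el, f"{{{PNML_NS}}}page", id="page0")

    def text_child(parent: etree._Element, tag: str, value: str) -> None:
        el = etree.SubElement(parent, f"{{{PNML_NS}}}{tag}")
        etree.SubElement(el, f"{{{PNML_NS}}}text").text = value

    for pid in sorted(net.places):
        el = etree.SubElement(page, f"{{{PNML_NS}}}place", id=pid)
        text_child(el, "name", net.place_name(pid))
        marking = net.initial_marking.get(pid, 0)
        if marking:
            text_child(el, "initialMarking", str(marking))
    for tid in sorted(net.transitions):
        el = etree.SubElement(page, f"{{{PNML_NS}}}transition", id=tid)
        text_child(el, "name", net.transition_name(tid))
    for i, (src, tgt, w) in enumerate(sorted(net.arcs)):
        el = etree.SubElement(page, f"{{{PNML_NS}}}arc", id=f"a{i}",
                              source=src, target=tgt)
        if w != 1:
            text_child(el, "inscription", str(w))
    payload = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                             pretty_print=True)
    if isinstance(stream, str):
        with open(stream, "wb") as fh:
            fh.write(payload)
    else:
        stream.write(payload)


# ---------------------------------------------------------------------------
# Snoopy .spped

def read_spped(stream: IO[bytes] | IO[str] | str) -> NetDocument:
    """Read a Snoopy discrete place/transition net (``.spped``).

    Node ids come from the ``id`` attributes; display names and markings from
    the ``Name``/``Marking`` attribute elements.  Place nodes sharing a
    display name are treated as logical copies of one place and merged, with
    arcs rewired onto the surviving place and parallel arcs summed.
    """
    root = _parse_xml(stream)
    netclass = None
    for el in root.iter():
        if _local(el.tag) == "netclass":
            netclass = el.get("name", "")
            break
    if netclass is None or "Petri Net" not in netclass:
        raise FormatError(
            f"unsupported Snoopy net class {netclass!r}: only discrete "
            "place/transition nets are readable"
        )
    if any(k in (netclass or "") for k in ("Continuous", "Stochastic", "Colored")):
        raise FormatError(f"unsupported Snoopy net class {netclass!r}")

    places: dict[str, tuple[str, int]] = {}      # node id -> (name, marking)
    transitions: dict[str, str] = {}
    for el in root.iter():
        if _local(el.tag) != "nodeclass":
            continue
        kind = el.get("name", "")
        for node in el:
            if _local(node.tag) != "node":
                continue
            nid = node.get("id")
            if nid is None:
                continue
            name = nid
            marking = 0
            for attr in node:
                if _local(attr.tag) == "attribute":
                    aname = attr.get("name", "")
                    text = (attr.text or "").strip()
                    if not text:  # value may sit in a CDATA child
                        text = "".join(attr.itertext()).strip()
                    if aname == "Name" and text:
                        name = text
                    elif aname == "Marking" and text:
                        marking = int(float(text))
            if kind == "Place":
                places[nid] = (name, marking)
            elif kind == "Transition":
                transitions[nid] = name

    if not places and not transitions:
        raise FormatError("no Place/Transition node classes found")

    # merge logical places: first node id with a given name survives
    canonical: dict[str, str] = {}
    surviving: dict[str, tuple[str, int]] = {}
    by_name: dict[str, str] = {}
    for nid, (name, marking) in places.items():
        if name in by_name:
            keep = by_name[name]
            canonical[nid] = keep
            old_name, old_marking = surviving[keep]
            surviving[keep] = (old_name, old_marking + marking)
        else:
            by_name[name] = nid
            canonical[nid] = nid
            surviving[nid] = (name, marking)

    net = PetriNet("spped")
    for nid, (name, marking) in surviving.items():
        net.add_place(nid, name, marking)
    for nid, name in transitions.items():
        net.add_transition(nid, name)

    arc_weights: dict[tuple[str, str], int] = {}
    for el in root.iter():
        if _local(el.tag) != "edge":
            continue
        src, tgt = el.get("source"), el.get("target")
        if src is None or tgt is None:
            continue
        weight = 1
        for attr in el:
            if _local(attr.tag) == "attribute" and attr.get("name") == "Multiplicity":
                text = "".join(attr.itertext()).strip()
                if text:
                    weight = int(float(text))
        src = canonical.get(src, src)
        tgt = canonical.get(tgt, tgt)
        if not (net.has_place(src) or net.has_transition(src)):
            raise FormatError(f"edge source {src!r} references no node")
        if not (net.has_place(tgt) or net.has_transition(tgt)):
            raise FormatError(f"edge target {tgt!r} references no node")
        arc_weights[(src, tgt)] = arc_weights.get((src, tgt), 0) + weight
    for (src, tgt), w in arc_weights.items():
        net.add_arc(src, tgt, w)
    return NetDocument(net, "spped", {"netclass": netclass})


# ---------------------------------------------------------------------------
# CSV arc list

def read_csv_arclist(stream: IO[str] | str) -> NetDocument:
    """Read a CSV arc list with header ``source,target[,weight]``.

    Node kind is inferred from the id prefix: ``p``/``P`` for places,
    ``t``/``T`` for transitions; any other prefix is rejected.  Duplicate
    rows are summed into one weighted arc with a warning.
    """
    if isinstance(stream, str):
        with open(stream, newline="") as fh:
            return read_csv_arclist(fh)
    reader = csv.DictReader(stream)
    fields = [f.strip().lower() for f in reader.fieldnames or []]
    if fields[:2] != ["source", "target"]:
        raise FormatError("CSV arc list requires header 'source,target[,weight]'")
    has_weight = "weight" in fields

    def classify(node_id: str) -> str:
        if node_id[:1] in ("p", "P"):
            return "place"
        if node_id[:1] in ("t", "T"):
            return "transition"
        raise FormatError(
            f"ambiguous id {node_id!r}: ids must start with p/P (place) or "
            "t/T (transition)"
        )

    net = PetriNet("csv")
    rows: list[tuple[str, str, int]] = []
    for lineno, row in enumerate(reader, start=2):
        src = (row.get("source") or "").strip()
        tgt = (row.get("target") or "").strip()
        if not src or not tgt:
            raise FormatError(f"line {lineno}: missing source/target")
        for node in (src, tgt):
            if classify(node) == "place":
                net.add_place(node)
            else:
                net.add_transition(node)
        if classify(src) == classify(tgt):
            raise FormatError(
                f"line {lineno}: arc {src!r}->{tgt!r} connects two "
                f"{classify(src)}s; nets are bipartite"
            )
        weight = 1
        if has_weight and (row.get("weight") or "").strip():
            weight = int(row["weight"])
        rows.append((src, tgt, weight))
    for src, tgt, weight in rows:
        net.add_arc(src, tgt, weight)   # duplicates warn + sum in PetriNet
    return NetDocument(net, "csv")


def read_net(path: str, fmt: str = "auto") -> NetDocument:
    """Dispatch on ``fmt`` or the file extension (.pnml/.xml, .spped, .csv)."""
    if fmt == "auto":
        lower = path.lower()
        if lower.endswith(".spped"):
            fmt = "spped"
        elif lower.endswith(".csv"):
            fmt = "csv"
        else:
            fmt = "pnml"
    if fmt == "pnml":
        return read_pnml(path)
    if fmt == "spped":
        return read_spped(path)
    if fmt == "csv":
        return read_csv_arclist(path)
    raise FormatError(f"unknown format {fmt!r}")
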