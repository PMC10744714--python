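"""Core Petri-net data model, validation, incidence matrix, and I/O.

A net is a bipartite directed weighted graph: places hold tokens, transitions
move them, arcs connect a place with a transition (never two nodes of the same
kind). The incidence matrix ``A`` has one row per place and one column per
transition; entry ``a[i, j]`` is the net token change of place ``i`` when
transition ``j`` fires.

Two interchange formats are supported: ISO/IEC 15909-2 PNML (PT-net dialect)
and a small native JSON schema that is convenient to edit by hand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from lxml import etree

__all__ = [
    "Place",
    "Transition",
    "Arc",
    "PetriNet",
    "Marking",
    "IncidenceMatrix",
    "ValidationReport",
    "NetFormatError",
    "build_incidence_matrix",
    "validate_structure",
    "read_net",
    "write_net",
    "incidence_to_tsv",
]


class NetFormatError(ValueError):
    """Raised when a net file cannot be parsed in the declared dialect."""


@dataclass(frozen=True)
class Place:
    id: str
    name: str = ""
    initial_tokens: int = 0
    is_logical: bool = False


@dataclass(frozen=True)
class Transition:
    id: str
    name: str = ""


@dataclass(frozen=True)
class Arc:
    source: str
    target: str
    weight: int = 1


@dataclass
class PetriNet:
    """Ordered collections of places/transitions plus the arc set."""

    places: list[Place]
    transitions: list[Transition]
    arcs: list[Arc]
    metadata: dict = field(default_factory=dict)

    @property
    def place_ids(self) -> list[str]:
        return [p.id for p in self.places]

    @property
    def transition_ids(self) -> list[str]:
        return [t.id for t in self.transitions]

    @property
    def n_places(self) -> int:
        return len(self.places)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def place(self, pid: str) -> Place:
        for p in self.places:
            if p.id == pid:
                return p
        raise KeyError(f"unknown place id: {pid}")

    def transition(self, tid: str) -> Transition:
        for t in self.transitions:
            if t.id == tid:
                return t
        raise KeyError(f"unknown transition id: {tid}")

    def pre_arcs(self, tid: str) -> list[Arc]:
        """Arcs from places into transition *tid*."""
        return [a for a in self.arcs if a.target == tid]

    def post_arcs(self, tid: str) -> list[Arc]:
        """Arcs from transition *tid* into places."""
        return [a for a in self.arcs if a.source == tid]

    def initial_marking(self) -> "Marking":
        return Marking({p.id: p.initial_tokens for p in self.places})

    def merge_logical_places(self) -> "PetriNet":
        """Collapse logical duplicates onto their primary place.

        Logical places are a drawing device: several circles in a figure that
        denote the same biological entity. A logical place carries, in its
        metadata-free form, the convention that its id is ``<primary>__<k>``.
        All arcs are re-pointed at the primary id before analysis.
        """
        mapping: dict[str, str] = {}
        keep: list[Place] = []
        for p in self.places:
            if p.is_logical and "__" in p.id:
                mapping[p.id] = p.id.split("__", 1)[0]
            else:
                keep.append(p)
        if not mapping:
            return self
        arcs = []
        seen = set()
        for a in self.arcs:
            a2 = Arc(mapping.get(a.source, a.source), mapping.get(a.target, a.target), a.weight)
            if (a2.source, a2.target) not in seen:
                seen.add((a2.source, a2.target))
                arcs.append(a2)
        return PetriNet(keep, list(self.transitions), arcs, dict(self.metadata))


@dataclass
class Marking:
    tokens: dict[str, int]

    def __getitem__(self, pid: str) -> int:
        return self.tokens.get(pid, 0)

    def copy(self) -> "Marking":
        return Marking(dict(self.tokens))


@dataclass
class IncidenceMatrix:
    entries: np.ndarray  # shape (n_places, n_transitions), dtype int64
    row_ids: list[str]
    col_ids: list[str]

    def column(self, tid: str) -> np.ndarray:
        return self.entries[:, self.col_ids.index(tid)]


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __iter__(self):
        return iter(self.violations)


def validate_structure(net: PetriNet) -> ValidationReport:
    """Check bipartiteness, id uniqueness, dangling endpoints, arc weights.

    Violations are report content, not exceptions, so that a model editor can
    display all problems at once.
    """
    rep = ValidationReport()
    pids = net.place_ids
    tids = net.transition_ids
    pset, tset = set(pids), set(tids)
    if len(pset) != len(pids):
        dupes = sorted({x for x in pids if pids.count(x) > 1})
        rep.violations.append(f"duplicate place ids: {dupes}")
    if len(tset) != len(tids):
        dupes = sorted({x for x in tids if tids.count(x) > 1})
        rep.violations.append(f"duplicate transition ids: {dupes}")
    if pset & tset:
        rep.violations.append(f"ids used for both a place and a transition: {sorted(pset & tset)}")
    for p in net.places:
        if p.initial_tokens < 0:
            rep.violations.append(f"place {p.id}: negative initial tokens")
    seen_pairs = set()
    for a in net.arcs:
        s_place, t_place = a.source in pset, a.target in pset
        s_trans, t_trans = a.source in tset, a.target in tset
        if not (s_place or s_trans):
            rep.violations.append(f"arc {a.source}->{a.target}: dangling source")
            continue
        if not (t_place or t_trans):
            rep.violations.append(f"arc {a.source}->{a.target}: dangling target")
            continue
        if s_place == t_place:
            kind = "place" if s_place else "transition"
            rep.violations.append(
                f"arc {a.source}->{a.target}: connects two {kind}s (bipartiteness violated)"
            )
        if a.weight < 1:
            rep.violations.append(f"arc {a.source}->{a.target}: non-positive weight {a.weight}")
        if (a.source, a.target) in seen_pairs:
            rep.violations.append(f"duplicate arc {a.source}->{a.target}")
        seen_pairs.add((a.source, a.target))
    return rep


def build_incidence_matrix(net: PetriNet) -> IncidenceMatrix:
    """Incidence matrix ``A`` with ``a[i, j] = w(t_j -> p_i) - w(p_i -> t_j)``.

    Raises ``ValueError`` if the net fails structural validation, naming the
    offending arc(s).
    """
    rep = validate_structure(net)
    if not rep.ok:
        raise ValueError("net fails structural validation: " + "; ".join(rep.violations))
    net = net.merge_logical_places()
    pindex = {p: i for i, p in enumerate(net.place_ids)}
    tindex = {t: j for j, t in enumerate(net.transition_ids)}
    A = np.zeros((net.n_places, net.n_transitions), dtype=np.int64)
    for a in net.arcs:
        if a.source in tindex:  # transition -> place: production
            A[pindex[a.target], tindex[a.source]] += a.weight
        else:  # place -> transition: consumption
            A[pindex[a.source], tindex[a.target]] -= a.weight
    return IncidenceMatrix(A, net.place_ids, net.transition_ids)


# ---------------------------------------------------------------------------
# native JSON format

def _net_to_dict(net: PetriNet) -> dict:
    d = {
        "places": [
            {"id": p.id, "name": p.name, "initial_tokens": p.initial_tokens,
             **({"is_logical": True} if p.is_logical else {})}
            for p in net.places
        ],
        "transitions": [{"id": t.id, "name": t.name} for t in net.transitions],
        "arcs": [{"source": a.source, "target": a.target, "weight": a.weight} for a in net.arcs],
    }
    if net.metadata:
        d["metadata"] = net.metadata
    return d


def _net_from_dict(d: Mapping) -> PetriNet:
    try:
        places = [
            Place(p["id"], p.get("name", ""), int(p.get("initial_tokens", 0)),
                  bool(p.get("is_logical", False)))
            for p in d["places"]
        ]
        transitions = [Transition(t["id"], t.get("name", "")) for t in d["transitions"]]
        arcs = [Arc(a["source"], a["target"], int(a.get("weight", 1))) for a in d["arcs"]]
    except (KeyError, TypeError) as exc:
        raise NetFormatError(f"malformed native-json net description: {exc}") from exc
    return PetriNet(places, transitions, arcs, dict(d.get("metadata", {})))


# ---------------------------------------------------------------------------
# PNML (PT-net dialect)

_PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"
_PTNET_TYPE = "http://www.pnml.org/version-2009/grammar/ptnet"


def _pnml_text(el, tag):
    node = el.find(f"{{{_PNML_NS}}}{tag}/{{{_PNML_NS}}}text")
    if node is None:  # tolerate un-namespaced documents
        node = el.find(f"{tag}/text")
    return node.text if node is not None else None


def _net_to_pnml(net: PetriNet) -> bytes:
    root = etree.Element(f"{{{_PNML_NS}}}pnml", nsmap={None: _PNML_NS})
    netel = etree.SubElement(root, f"{{{_PNML_NS}}}net",
                             id=net.metadata.get("name", "net0"), type=_PTNET_TYPE)
    page = etree.SubElement(netel, f"{{{_PNML_NS}}}page", id="page0")

    def add_name(parent, text):
        if text:
            nm = etree.SubElement(parent, f"{{{_PNML_NS}}}name")
            etree.SubElement(nm, f"{{{_PNML_NS}}}text").text = text

    for p in net.places:
        pel = etree.SubElement(page, f"{{{_PNML_NS}}}place", id=p.id)
        add_name(pel, p.name)
        if p.initial_tokens:
            mk = etree.SubElement(pel, f"{{{_PNML_NS}}}initialMarking")
            etree.SubElement(mk, f"{{{_PNML_NS}}}text").text = str(p.initial_tokens)
    for t in net.transitions:
        tel = etree.SubElement(page, f"{{{_PNML_NS}}}transition", id=t.id)
        add_name(tel, t.name)
    for i, a in enumerate(net.arcs):
        ael = etree.SubElement(page, f"{{{_PNML_NS}}}arc", id=f"a{i}",
                               source=a.source, target=a.target)
        if a.weight != 1:
            ins = etree.SubElement(ael, f"{{{_PNML_NS}}}inscription")
            etree.SubElement(ins, f"{{{_PNML_NS}}}text").text = str(a.weight)
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def _net_from_pnml(data: bytes, path: str = "<pnml>") -> PetriNet:
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise NetFormatError(f"{path}: not well-formed XML ({exc})") from exc
    netel = root.find(f"{{{_PNML_NS}}}net")
    if netel is None:
        netel = root.find("net")
    if netel is None:
        raise NetFormatError(f"{path}: no <net> element found")
    nettype = netel.get("type", _PTNET_TYPE)
    if "ptnet" not in nettype:
        raise NetFormatError(f"{path}: unsupported net type {nettype!r} (PT nets only)")
    places, transitions, arcs = [], [], []
    for el in netel.iter():
        tag = etree.QName(el).localname
        if tag == "place":
            tokens = _pnml_text(el, "initialMarking")
            places.append(Place(el.get("id"), _pnml_text(el, "name") or "",
                                int(tokens) if tokens else 0))
        elif tag == "transition":
            transitions.append(Transition(el.get("id"), _pnml_text(el, "name") or ""))
        elif tag == "arc":
            w = _pnml_text(el, "inscription")
            # PT-net convention: a missing inscription means weight 1
            arcs.append(Arc(el.get("source"), el.get("target"), int(w) if w else 1))
    return PetriNet(places, transitions, arcs, {"name": netel.get("id", "net0")})


# ---------------------------------------------------------------------------

def read_net(path: str | Path, format: str | None = None) -> PetriNet:
    """Read a net from *path*; the format is inferred from the suffix unless given."""
    path = Path(path)
    fmt = format or ("pnml" if path.suffix.lower() in (".pnml", ".xml") else "native-json")
    if fmt == "pnml":
        return _net_from_pnml(path.read_bytes(), str(path))
    if fmt == "native-json":
        try:
            d = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise NetFormatError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
        return _net_from_dict(d)
    raise NetFormatError(f"unsupported net format: {fmt!r}")


def write_net(net: PetriNet, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("pnml" if path.suffix.lower() in (".pnml", ".xml") else "native-json")
    if fmt == "pnml":
        path.write_bytes(_net_to_pnml(net))
    elif fmt == "native-json":
        path.write_text(json.dumps(_net_to_dict(net), indent=1) + "\n")
    else:
        raise NetFormatError(f"unsupported net format: {fmt!r}")


def incidence_to_tsv(inc: IncidenceMatrix) -> str:
    """TSV rendering: header row = transition ids, first column = place ids."""
    lines = ["\t".join([""] + inc.col_ids)]
    for pid, row in zip(inc.row_ids, inc.entries):
        lines.append("\t".join([pid] + [str(int(v)) for v in row]))
    return "\n".join(lines) + "\n"
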