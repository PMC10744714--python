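"""Maximal common transition (MCT) sets.

Two transitions belong to the same MCT set when they occur in exactly the
same t-invariant supports; the classes of this equivalence partition the
covered transitions. Non-trivial sets (more than one member) are read as
functional building blocks of the modelled system and are labelled m1, m2, ...
by decreasing size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .invariants import TInvariantSet
from .net import PetriNet

__all__ = ["MCTSet", "mct_partition", "label_mct"]


@dataclass
class MCTSet:
    label: str
    members: frozenset[str]
    signature: frozenset[int]  # indices of invariants containing the members
    annotation: str = ""

    @property
    def trivial(self) -> bool:
        return len(self.members) == 1


def mct_partition(invs: TInvariantSet, net: PetriNet) -> list[MCTSet]:
    """Group transitions by identical containing-invariant signature.

    Uncovered transitions (empty signature) are not partitioned; they are
    returned as a separate class labelled ``uncovered`` so callers can report
    them, never silently merged with covered classes.
    """
    if set(invs.transition_ids) != set(net.transition_ids):
        raise ValueError("invariant set does not belong to this net")
    sig: dict[str, set[int]] = {t: set() for t in net.transition_ids}
    for i, inv in enumerate(invs):
        for t in inv.support:
            sig[t].add(i)
    groups: dict[frozenset[int], set[str]] = {}
    for t, s in sig.items():
        groups.setdefault(frozenset(s), set()).add(t)
    out = []
    for s, members in groups.items():
        label = "uncovered" if not s else ""
        out.append(MCTSet(label, frozenset(members), s))
    return label_mct(out, net)


def _member_sort_key(net: PetriNet):
    order = {t: i for i, t in enumerate(net.transition_ids)}
    return order


def label_mct(partition: list[MCTSet], net: PetriNet) -> list[MCTSet]:
    """Assign m1..mk to non-trivial sets, sorted by (size desc, min member asc).

    Trivial sets are labelled ``trivial:<transition-id>`` and retained: single
    transitions are legitimate knockout units. The ordering rule makes labels
    reproducible across runs.
    """
    order = _member_sort_key(net)
    nontrivial = [g for g in partition if len(g.members) > 1 and g.label != "uncovered"]
    trivial = [g for g in partition if len(g.members) == 1 and g.label != "uncovered"]
    rest = [g for g in partition if g.label == "uncovered"]
    nontrivial.sort(key=lambda g: (-len(g.members), min(order[t] for t in g.members)))
    for k, g in enumerate(nontrivial, start=1):
        g.label = f"m{k}"
    for g in trivial:
        g.label = f"trivial:{next(iter(g.members))}"
    trivial.sort(key=lambda g: order[next(iter(g.members))])
    return nontrivial + trivial + rest


def resolve_knock_ids(ids, partition: list[MCTSet], net: PetriNet) -> set[str]:
    """Expand a mix of transition ids and MCT labels into a transition set."""
    by_label = {g.label: g for g in partition}
    tset = set(net.transition_ids)
    out: set[str] = set()
    for ident in ids:
        if ident in tset:
            out.add(ident)
        elif ident in by_label:
            out |= by_label[ident].members
        else:
            raise KeyError(f"unknown transition or MCT label: {ident}")
    return out
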