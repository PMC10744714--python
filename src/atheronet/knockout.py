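"""t-invariant-based knockout analysis.

Knocking out a transition set K removes every invariant whose support meets
K ("affected" invariants). A transition is *affected* when it occurs only in
supports of affected invariants, i.e. it survives in no remaining support.
The impact of a knockout is summarised by the affected-transition percentage
(over all m transitions) and, for a chosen target transition, by how many
remaining invariants still contain the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

from .invariants import TInvariantSet, invariants_containing
from .mct import MCTSet
from .net import PetriNet

__all__ = [
    "KnockoutSpec",
    "ScenarioResult",
    "run_knockout",
    "knockout_impact_table",
    "scenario_sweep",
    "percent",
]


def percent(numerator: int, denominator: int) -> float:
    """Two-decimal half-up percentage, the convention used in the reports."""
    if denominator == 0:
        return 0.0
    q = Decimal(numerator) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class KnockoutSpec:
    knocked: frozenset[str]
    label: str = ""

    def __post_init__(self):
        if not self.knocked:
            raise ValueError("knockout set must be nonempty")


@dataclass
class ScenarioResult:
    spec: KnockoutSpec
    target: str
    affected_invariants: list[int]
    remaining_invariants: list[int]
    affected_transitions: list[str]
    disabled_mct: list[str]
    remaining_with_target: int
    percentage_incl: float  # |affected transitions| / m
    percentage_excl: float  # |affected transitions \ K| / m

    @property
    def n_remaining(self) -> int:
        return len(self.remaining_invariants)


def run_knockout(invs: TInvariantSet, net: PetriNet, spec: KnockoutSpec,
                 target: str, partition: Sequence[MCTSet] = ()) -> ScenarioResult:
    """Apply the invariant-based knockout *spec* and measure its impact.

    ``partition`` is optional; when given, MCT sets wholly inside the affected
    transitions are reported by label.
    """
    tset = set(net.transition_ids)
    unknown = set(spec.knocked) - tset
    if unknown:
        raise KeyError(f"unknown transition id(s) in knockout: {sorted(unknown)}")
    if target not in tset:
        raise KeyError(f"unknown target transition: {target}")
    affected, remaining = [], []
    for i, inv in enumerate(invs):
        (affected if inv.support & spec.knocked else remaining).append(i)
    surviving: set[str] = set()
    for i in remaining:
        surviving |= invs[i].support
    affected_transitions = [t for t in net.transition_ids if t not in surviving]
    m = net.n_transitions
    with_target = sum(1 for i in remaining if target in invs[i].support)
    aff_set = set(affected_transitions)
    disabled = [g.label for g in partition
                if not g.trivial and g.members <= aff_set]
    return ScenarioResult(
        spec=spec,
        target=target,
        affected_invariants=affected,
        remaining_invariants=remaining,
        affected_transitions=affected_transitions,
        disabled_mct=disabled,
        remaining_with_target=with_target,
        percentage_incl=percent(len(affected_transitions), m),
        percentage_excl=percent(len(aff_set - spec.knocked), m),
    )


def knockout_impact_table(invs: TInvariantSet, net: PetriNet,
                          specs: Iterable[KnockoutSpec], target: str,
                          partition: Sequence[MCTSet] = ()) -> list[dict]:
    """One row per knockout spec, ranked by inclusive percentage descending.

    Single-transition rows report one percentage; multi-transition (MCT) rows
    report both the inclusive and the knocked-set-excluded convention.
    """
    rows = []
    for spec in specs:
        res = run_knockout(invs, net, spec, target, partition)
        row = {
            "label": spec.label or "+".join(sorted(spec.knocked)),
            "knocked": sorted(spec.knocked),
            "n_affected_transitions": len(res.affected_transitions),
            "percentage_incl": res.percentage_incl,
            "n_remaining_invariants": res.n_remaining,
            "remaining_with_target": res.remaining_with_target,
        }
        if len(spec.knocked) > 1:
            row["percentage_excl"] = res.percentage_excl
        rows.append(row)
    rows.sort(key=lambda r: (-r["percentage_incl"], r["label"]))
    return rows


def scenario_sweep(invs: TInvariantSet, net: PetriNet, catalog: Iterable,
                   partition: Sequence[MCTSet] = ()) -> list[dict]:
    """Run every scenario of a catalog; report counts and percentages.

    Catalog entries carry ``name``, ``knocked`` and ``target`` attributes (see
    :mod:`atheronet.disease_model`). Percentages are relative to the total
    invariant count and to the unperturbed with-target count, mirroring the
    scenario table layout of the reference analysis.
    """
    n_total = len(invs)
    rows = []
    for sc in catalog:
        target = sc.target
        base_with_target = len(invariants_containing(invs, {target}))
        res = run_knockout(invs, net, KnockoutSpec(frozenset(sc.knocked), sc.name),
                           target, partition)
        aff = set(res.affected_transitions)
        in_mct = set()
        for g in res.disabled_mct:
            for grp in partition:
                if grp.label == g:
                    in_mct |= grp.members
        rows.append({
            "scenario": sc.name,
            "knocked": sorted(sc.knocked),
            "disabled_mct": res.disabled_mct,
            "disabled_transitions": sorted(aff - in_mct),
            "n_remaining": res.n_remaining,
            "pct_remaining": percent(res.n_remaining, n_total),
            "remaining_with_target": res.remaining_with_target,
            "pct_remaining_with_target": percent(res.remaining_with_target,
                                                 base_with_target),
        })
    return rows
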