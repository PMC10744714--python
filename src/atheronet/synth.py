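"""Synthetic nets with known invariant structure, and a brute-force oracle.

Cycle nets have a closed-form answer (one all-ones minimal t-invariant), and
random bipartite nets — optionally repaired until they are covered by
t-invariants — exercise the exact engines on structures nobody hand-tuned.
The bounded brute-force enumerator is deliberately naive; it exists so that
tests can compare the Fourier-Motzkin engine against an independent
computation on small nets.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np

from .invariants import TInvariant, TInvariantSet
from .net import Arc, IncidenceMatrix, PetriNet, Place, Transition

__all__ = [
    "GeneratorParams",
    "make_cycle_net",
    "make_random_net",
    "brute_force_invariants",
    "OracleInfeasible",
]


class OracleInfeasible(RuntimeError):
    """The brute-force enumeration budget would be exceeded."""


@dataclass(frozen=True)
class GeneratorParams:
    n_places: int = 4
    n_transitions: int = 5
    density: float = 0.3
    max_weight: int = 1
    seed: int = 0
    ensure_covered: bool = False

    def __post_init__(self):
        if self.n_places < 1 or self.n_transitions < 1:
            raise ValueError("need at least one place and one transition")
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if self.max_weight < 1:
            raise ValueError("max_weight must be >= 1")


def make_cycle_net(k: int) -> PetriNet:
    """Alternating cycle p0 -> t0 -> p1 -> t1 -> ... -> p0 with unit weights.

    Its unique minimal t-invariant is the all-ones vector.
    """
    if k < 1:
        raise ValueError("cycle length must be >= 1")
    places = [Place(f"p{i}", initial_tokens=1 if i == 0 else 0) for i in range(k)]
    transitions = [Transition(f"t{i}") for i in range(k)]
    arcs = []
    for i in range(k):
        arcs.append(Arc(f"p{i}", f"t{i}"))
        arcs.append(Arc(f"t{i}", f"p{(i + 1) % k}"))
    return PetriNet(places, transitions, arcs, {"name": f"cycle{k}"})


def disjoint_union(a: PetriNet, b: PetriNet, rename: str = "b_") -> PetriNet:
    """Union of two nets with *b*'s ids prefixed to keep them disjoint."""
    places = list(a.places) + [Place(rename + p.id, p.name, p.initial_tokens) for p in b.places]
    transitions = list(a.transitions) + [Transition(rename + t.id, t.name) for t in b.transitions]
    arcs = list(a.arcs) + [Arc(rename + x.source, rename + x.target, x.weight) for x in b.arcs]
    return PetriNet(places, transitions, arcs, {"name": f"{a.metadata.get('name')}+{b.metadata.get('name')}"})


def make_random_net(params: GeneratorParams) -> PetriNet:
    """Sample a bipartite net; optionally inject cycles until it is covered.

    Bipartiteness holds by construction: arcs are drawn only between the
    place set and the transition set. With ``ensure_covered`` the generator
    threads random place-transition cycles through uncovered transitions
    until every transition sits on at least one invariant support; this
    terminates because each injected cycle covers its member transitions.
    """
    rng = np.random.default_rng(params.seed)
    places = [Place(f"p{i}", initial_tokens=int(rng.integers(0, 3)))
              for i in range(params.n_places)]
    transitions = [Transition(f"t{j}") for j in range(params.n_transitions)]
    arcs: dict[tuple[str, str], int] = {}
    for p in places:
        for t in transitions:
            if rng.random() < params.density:
                arcs[(p.id, t.id)] = int(rng.integers(1, params.max_weight + 1))
            if rng.random() < params.density:
                arcs[(t.id, p.id)] = int(rng.integers(1, params.max_weight + 1))
    net = PetriNet(places, transitions,
                   [Arc(s, t, w) for (s, t), w in sorted(arcs.items())],
                   {"name": f"random{params.seed}"})
    if not params.ensure_covered:
        return net
    from .invariants import coverage_check, minimal_t_invariants
    from .net import build_incidence_matrix
    for _ in range(params.n_transitions + 1):
        invs = minimal_t_invariants(build_incidence_matrix(net))
        ok, uncovered = coverage_check(invs, net)
        if ok:
            return net
        # thread a unit-weight cycle through the first uncovered transition
        t = uncovered[0]
        p_in = places[int(rng.integers(len(places)))].id
        p_out = places[int(rng.integers(len(places)))].id
        need = {(p_in, t), (t, p_out), (p_out, f"t_fix_{t}"), (f"t_fix_{t}", p_in)}
        if f"t_fix_{t}" not in [x.id for x in net.transitions]:
            net.transitions.append(Transition(f"t_fix_{t}"))
        have = {(a.source, a.target) for a in net.arcs}
        for s, tt in need:
            if (s, tt) not in have:
                net.arcs.append(Arc(s, tt, 1))
    return net


def brute_force_invariants(A: IncidenceMatrix, bound: int = 6,
                           budget: int = 5_000_000) -> TInvariantSet:
    """Enumerate every x in {0..bound}^m, keep A x = 0, reduce and minimise.

    Test oracle only; refuses instances where ``(bound+1)**m`` exceeds
    *budget* instead of silently taking forever.
    """
    m = len(A.col_ids)
    total = (bound + 1) ** m
    if total > budget:
        raise OracleInfeasible(f"(bound+1)^m = {total} exceeds budget {budget}")
    mat = A.entries.astype(np.int64)
    # vectorised enumeration in batches: grid of all vectors in {0..bound}^m
    sols = []
    batch = 1 << 16
    ranges = [np.arange(bound + 1, dtype=np.int64)] * m
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, m)
    for lo in range(0, len(grid), batch):
        X = grid[lo:lo + batch]
        ok = np.all(mat @ X.T == 0, axis=0) & np.any(X, axis=1)
        for x in X[ok]:
            g = 0
            for v in x:
                g = gcd(g, int(v))
            sols.append(tuple(int(v) // g for v in x))
    uniq = set(sols)
    sups = {x: frozenset(j for j, v in enumerate(x) if v) for x in uniq}
    minimal = [x for x in uniq if not any(sups[y] < sups[x] for y in uniq if y != x)]
    tids = tuple(A.col_ids)
    invs = [TInvariant(x, tids) for x in minimal]
    invs.sort(key=lambda inv: sorted(inv.support_indices()))
    return TInvariantSet(invs, list(A.col_ids))
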