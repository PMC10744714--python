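"""Exact enumeration of minimal t-invariants.

A t-invariant is a nonnegative integer vector ``x`` with ``A @ x == 0``; firing
every transition ``t_j`` of its support ``s(x) = {t_j : x_j > 0}`` exactly
``x_j`` times returns the net to the marking it started from, so invariants
are read as self-contained subprocesses. "Minimal" means support-minimal with
the nonzero entries scaled to gcd 1.

The enumeration is the classical Farkas / Fourier-Motzkin place-by-place
elimination: keep a row set ``[x | A^T x]``, and at every step combine
positive- with negative-signed rows of one place column so that the column
becomes zero, discarding rows whose support is a superset of another row's.
All arithmetic is exact (Python ints via object arrays are avoided; int64 is
sufficient for nets of this scale and overflow is checked).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd
from typing import Iterable, Sequence

import numpy as np

from .net import IncidenceMatrix, PetriNet

__all__ = [
    "TInvariant",
    "TInvariantSet",
    "InvariantComputationError",
    "minimal_t_invariants",
    "coverage_check",
    "invariants_containing",
    "invariants_touching_place",
]


class InvariantComputationError(RuntimeError):
    """Raised when the elimination exceeds its configured resource budget."""


@dataclass(frozen=True)
class TInvariant:
    multiplicities: tuple[int, ...]
    transition_ids: tuple[str, ...]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(t for t, x in zip(self.transition_ids, self.multiplicities) if x > 0)

    def support_indices(self) -> frozenset[int]:
        return frozenset(j for j, x in enumerate(self.multiplicities) if x > 0)

    def __getitem__(self, tid: str) -> int:
        return self.multiplicities[self.transition_ids.index(tid)]


@dataclass
class TInvariantSet:
    invariants: list[TInvariant]
    transition_ids: list[str]
    net_ref: str = ""

    def __len__(self) -> int:
        return len(self.invariants)

    def __iter__(self):
        return iter(self.invariants)

    def __getitem__(self, i: int) -> TInvariant:
        return self.invariants[i]

    def supports(self) -> list[frozenset[str]]:
        return [inv.support for inv in self.invariants]

    def subset(self, keep: Iterable[int]) -> "TInvariantSet":
        keep = sorted(keep)
        return TInvariantSet([self.invariants[i] for i in keep], list(self.transition_ids),
                             self.net_ref)

    def to_rows(self) -> list[dict]:
        return [
            {"index": i, "multiplicities": list(inv.multiplicities),
             "support": sorted(inv.support, key=self.transition_ids.index)}
            for i, inv in enumerate(self.invariants)
        ]


def _reduce_gcd(row: np.ndarray) -> np.ndarray:
    g = 0
    for v in row:
        g = gcd(g, int(v))
    return row // g if g > 1 else row


def _support_minimal_insert(rows: list[np.ndarray], supports: list[frozenset[int]],
                            cand: np.ndarray, m: int) -> None:
    """Insert *cand* unless its x-support strictly contains an existing row's.

    Rows whose support strictly contains the candidate's are dropped; exact
    duplicates are dropped. Equal supports with different multiplicities are
    both kept — intermediate rows are not yet solutions, and the final
    minimality filter resolves them.
    """
    s = frozenset(int(j) for j in np.nonzero(cand[:m])[0])
    if not s:
        return
    kill = []
    for i, t in enumerate(supports):
        if t < s:
            return
        if t == s and np.array_equal(rows[i], cand):
            return
        if s < t:
            kill.append(i)
    for i in reversed(kill):
        del rows[i]
        del supports[i]
    rows.append(cand)
    supports.append(s)


def minimal_t_invariants(A: IncidenceMatrix, *, max_rows: int = 200_000) -> TInvariantSet:
    """All support-minimal canonical nonnegative integer solutions of ``A x = 0``.

    Parameters
    ----------
    A:
        Incidence matrix (places x transitions).
    max_rows:
        Resource guard on the intermediate row count; exceeded means the net
        is too large for exact enumeration and an
        :class:`InvariantComputationError` is raised.

    The output ordering is deterministic: lexicographic by sorted support
    indices.
    """
    mat = A.entries
    n_places, m = mat.shape
    # working rows: identity | A^T
    X = np.eye(m, dtype=np.int64)
    C = mat.T.copy().astype(np.int64)
    rows = [np.concatenate([X[j], C[j]]) for j in range(m)]
    remaining = list(range(n_places))

    while remaining:
        # eliminate the place whose positive x negative row-product is least,
        # a standard heuristic to limit intermediate blow-up
        def cost(p):
            col = np.array([r[m + p] for r in rows])
            return int((col > 0).sum()) * int((col < 0).sum())

        p = min(remaining, key=cost)
        remaining.remove(p)
        pos = [r for r in rows if r[m + p] > 0]
        neg = [r for r in rows if r[m + p] < 0]
        zero = [r for r in rows if r[m + p] == 0]
        new_rows: list[np.ndarray] = []
        new_sups: list[frozenset[int]] = []
        for r in zero:
            _support_minimal_insert(new_rows, new_sups, r, m)
        for rp in pos:
            a = int(rp[m + p])
            for rn in neg:
                b = -int(rn[m + p])
                g = gcd(a, b)
                comb = (b // g) * rp + (a // g) * rn
                if np.any(np.abs(comb) > np.iinfo(np.int64).max // (2 * m + 2)):
                    raise InvariantComputationError("integer growth beyond safe range")
                comb = _reduce_gcd(comb)
                _support_minimal_insert(new_rows, new_sups, comb, m)
                if len(new_rows) > max_rows:
                    raise InvariantComputationError(
                        f"net too large for exact enumeration (> {max_rows} intermediate rows)"
                    )
        rows = new_rows

    candidates = []
    for r in rows:
        x = _reduce_gcd(r[:m].copy())
        if np.any(x < 0) or not np.any(x):
            continue
        assert np.all(mat @ x == 0), "internal error: produced vector is not an invariant"
        candidates.append(x)
    # final support-minimality filter + dedup, deterministic ordering
    uniq = {tuple(int(v) for v in x) for x in candidates}
    sups = {x: frozenset(j for j, v in enumerate(x) if v) for x in uniq}
    minimal = [x for x in uniq
               if not any(sups[y] < sups[x] for y in uniq if y != x)]
    tids = tuple(A.col_ids)
    invs = [TInvariant(x, tids) for x in minimal]
    invs.sort(key=lambda inv: sorted(inv.support_indices()))
    return TInvariantSet(invs, list(A.col_ids))


def coverage_check(invs: TInvariantSet, net: PetriNet) -> tuple[bool, list[str]]:
    """Is every transition in at least one invariant support?

    Returns ``(flag, uncovered_ids)`` with ``flag`` true iff the uncovered
    list is empty. Nets modelling biological systems are expected to be
    covered (CTI); an uncovered transition usually indicates a modelling gap.
    """
    if set(invs.transition_ids) != set(net.transition_ids):
        raise ValueError("invariant set does not belong to this net")
    covered: set[str] = set()
    for inv in invs:
        covered |= inv.support
    uncovered = [t for t in net.transition_ids if t not in covered]
    return (not uncovered, uncovered)


def invariants_containing(invs: TInvariantSet, targets: Iterable[str]) -> TInvariantSet:
    """Subset of invariants whose support meets *targets*; empty targets -> empty set."""
    targets = set(targets)
    unknown = targets - set(invs.transition_ids)
    if unknown:
        raise KeyError(f"unknown transition id(s): {sorted(unknown)}")
    if not targets:
        return TInvariantSet([], list(invs.transition_ids), invs.net_ref)
    keep = [i for i, inv in enumerate(invs) if inv.support & targets]
    return invs.subset(keep)


def invariants_touching_place(invs: TInvariantSet, net: PetriNet, place_id: str,
                              mode: str = "both") -> TInvariantSet:
    """Invariants whose support meets the transitions adjacent to *place_id*.

    ``mode`` selects the adjacency convention and is always explicit:
    ``producers`` (transitions with an arc into the place), ``consumers``
    (transitions the place feeds), or ``both``.
    """
    if place_id not in net.place_ids:
        raise KeyError(f"unknown place id: {place_id}")
    if mode not in ("producers", "consumers", "both"):
        raise ValueError(f"mode must be producers/consumers/both, got {mode!r}")
    producers = {a.source for a in net.arcs if a.target == place_id}
    consumers = {a.target for a in net.arcs if a.source == place_id}
    adjacent = {"producers": producers, "consumers": consumers,
                "both": producers | consumers}[mode]
    if not adjacent:
        return TInvariantSet([], list(invs.transition_ids), invs.net_ref)
    return invariants_containing(invs, adjacent)
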