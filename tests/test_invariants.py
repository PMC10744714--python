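"""Minimal t-invariant enumeration against closed forms and the brute-force oracle."""

import numpy as np
import pytest

from atheronet.invariants import (InvariantComputationError, coverage_check,
                                  invariants_containing, invariants_touching_place,
                                  minimal_t_invariants)
from atheronet.net import Arc, PetriNet, Place, Transition, build_incidence_matrix
from atheronet.synth import brute_force_invariants, disjoint_union, make_cycle_net
from conftest import random_nets


def invariant_vectors(invs):
    return {tuple(i.multiplicities) for i in invs}


def test_single_cycle_has_unique_all_ones_invariant(cycle2):
    invs = minimal_t_invariants(build_incidence_matrix(cycle2))
    assert invariant_vectors(invs) == {(1, 1)}


def test_disjoint_cycles_decompose():
    net = disjoint_union(make_cycle_net(2), make_cycle_net(3))
    invs = minimal_t_invariants(build_incidence_matrix(net))
    assert invariant_vectors(invs) == {(1, 1, 0, 0, 0), (0, 0, 1, 1, 1)}


def test_non_unit_weights_scale_multiplicities():
    # t0 makes two tokens on p0, t1 consumes one: x = (1, 2)
    net = PetriNet([Place("p0")], [Transition("t0"), Transition("t1")],
                   [Arc("t0", "p0", 2), Arc("p0", "t1")])
    invs = minimal_t_invariants(build_incidence_matrix(net))
    assert invariant_vectors(invs) == {(1, 2)}


def test_engine_matches_brute_force_oracle_on_100_random_nets():
    """Farkas elimination equals independent bounded enumeration."""
    for net in random_nets(100, max_weight=2):
        A = build_incidence_matrix(net)
        engine = {v for v in invariant_vectors(minimal_t_invariants(A))
                  if max(v) <= 6}
        oracle = invariant_vectors(brute_force_invariants(A, bound=6))
        assert engine == oracle, net.metadata


def test_every_returned_vector_is_an_exact_solution_and_minimal():
    for net in random_nets(40, max_weight=3):
        A = build_incidence_matrix(net)
        invs = minimal_t_invariants(A)
        sups = invs.supports()
        for inv in invs:
            x = np.array(inv.multiplicities)
            assert np.all(A.entries @ x == 0)
            assert np.all(x >= 0) and x.any()
            g = np.gcd.reduce(x[x > 0])
            assert g == 1
        for i, a in enumerate(sups):
            for j, b in enumerate(sups):
                assert i == j or not a < b


def test_permutation_equivariance():
    for net in random_nets(10, max_weight=2):
        perm_net = PetriNet(net.places, list(reversed(net.transitions)), net.arcs)
        a = invariant_vectors(minimal_t_invariants(build_incidence_matrix(net)))
        b = invariant_vectors(minimal_t_invariants(build_incidence_matrix(perm_net)))
        assert {tuple(reversed(v)) for v in b} == a


def test_deterministic_output_order():
    for net in random_nets(10, max_weight=2):
        A = build_incidence_matrix(net)
        r1 = minimal_t_invariants(A)
        r2 = minimal_t_invariants(A)
        assert [i.multiplicities for i in r1] == [i.multiplicities for i in r2]
        keys = [sorted(i.support_indices()) for i in r1]
        assert keys == sorted(keys)


def test_resource_guard_raises_cleanly():
    net = make_cycle_net(30)
    # absurdly low cap: the guard must fail loudly, not loop forever
    with pytest.raises(InvariantComputationError, match="too large"):
        minimal_t_invariants(build_incidence_matrix(net), max_rows=0)


def test_coverage_check_and_uncovered_listing(cycle2):
    invs = minimal_t_invariants(build_incidence_matrix(cycle2))
    assert coverage_check(invs, cycle2) == (True, [])
    # a source transition feeding a sink place can never recur
    net = PetriNet([Place("p0"), Place("p1")],
                   [Transition("t0"), Transition("t1"), Transition("t_src")],
                   [Arc("p0", "t0"), Arc("t0", "p1"), Arc("p1", "t1"), Arc("t1", "p0"),
                    Arc("t_src", "p1")])
    invs = minimal_t_invariants(build_incidence_matrix(net))
    assert coverage_check(invs, net) == (False, ["t_src"])


def test_invariants_containing_selects_by_support(cycle2):
    invs = minimal_t_invariants(build_incidence_matrix(cycle2))
    assert len(invariants_containing(invs, {"t0"})) == 1
    assert len(invariants_containing(invs, set())) == 0
    with pytest.raises(KeyError, match="t99"):
        invariants_containing(invs, {"t99"})


def test_invariants_touching_place_modes_match_direct_filter():
    for net in random_nets(25, max_weight=2):
        A = build_incidence_matrix(net)
        invs = minimal_t_invariants(A)
        for pid in net.place_ids:
            producers = {a.source for a in net.arcs if a.target == pid}
            consumers = {a.target for a in net.arcs if a.source == pid}
            for mode, adj in [("producers", producers), ("consumers", consumers),
                              ("both", producers | consumers)]:
                got = invariants_touching_place(invs, net, pid, mode)
                want = [i for i in invs if i.support & adj]
                assert list(got) == want


def test_touching_place_rejects_unknown_place_and_mode(cycle2):
    invs = minimal_t_invariants(build_incidence_matrix(cycle2))
    with pytest.raises(KeyError):
        invariants_touching_place(invs, cycle2, "p9")
    with pytest.raises(ValueError):
        invariants_touching_place(invs, cycle2, "p0", "upstream")
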