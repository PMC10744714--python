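"""Token-game simulator: firing rule, determinism, conservation, knockouts."""

import numpy as np
import pytest

from atheronet.net import Arc, Marking, PetriNet, Place, Transition
from atheronet.simulation import (SimulationConfig, enabled_transitions, fire,
                                  knockout_simulation_compare, simulate)
from atheronet.synth import make_cycle_net
from conftest import random_nets


def test_enabling_follows_arc_weights(cycle2):
    m = Marking({"p0": 1, "p1": 0})
    assert enabled_transitions(cycle2, m) == {"t0"}
    heavy = PetriNet([Place("p0")], [Transition("t0")], [Arc("p0", "t0", 2)])
    assert enabled_transitions(heavy, Marking({"p0": 1})) == set()
    source = PetriNet([Place("p0")], [Transition("t_in")], [Arc("t_in", "p0")])
    assert enabled_transitions(source, Marking({"p0": 0})) == {"t_in"}


def test_fire_moves_weighted_tokens(cycle2, fork_net):
    m = fire(cycle2, Marking({"p0": 1, "p1": 0}), "t0")
    assert m.tokens == {"p0": 0, "p1": 1}
    m = fire(fork_net, Marking({"p0": 1, "p1": 0}), "t0")
    assert m.tokens == {"p0": 0, "p1": 2}
    with pytest.raises(ValueError, match="not enabled"):
        fire(cycle2, Marking({"p0": 0, "p1": 0}), "t0")


def test_cycle_net_firing_counts_alternate():
    net = make_cycle_net(2)
    cfg = SimulationConfig(steps=100, replicates=3, seed=5)
    tr = simulate(net, cfg)
    assert np.all(np.abs(tr.firing_counts - 50) <= 1)
    assert all(s is None for s in tr.stalled_at)


def test_disabling_the_only_enabled_transition_stalls():
    net = make_cycle_net(2)
    cfg = SimulationConfig(steps=50, replicates=2, seed=1,
                           disabled=frozenset({"t0"}))
    tr = simulate(net, cfg)
    assert np.all(tr.firing_counts == 0)
    assert all(s == 0 for s in tr.stalled_at)


def test_seed_determinism_and_seed_sensitivity():
    for net in random_nets(5, ensure_covered=True):
        cfg = SimulationConfig(steps=60, replicates=4, seed=9)
        a, b = simulate(net, cfg), simulate(net, cfg)
        assert np.array_equal(a.firing_counts, b.firing_counts)
        assert np.array_equal(a.final_tokens, b.final_tokens)


def test_tokens_never_negative_and_disabled_never_fire():
    for net in random_nets(8, ensure_covered=True):
        dis = frozenset(net.transition_ids[:1])
        cfg = SimulationConfig(steps=40, replicates=3, seed=2, disabled=dis,
                               policy="maximal-random")
        tr = simulate(net, cfg)
        assert np.all(tr.final_tokens >= 0)
        assert np.all(tr.token_series >= 0)
        j = tr.transition_ids.index(next(iter(dis)))
        assert np.all(tr.firing_counts[:, j] == 0)


def test_conservative_net_keeps_total_tokens():
    net = make_cycle_net(5)  # every transition moves exactly one token
    cfg = SimulationConfig(steps=200, replicates=2, seed=3)
    tr = simulate(net, cfg)
    assert np.all(tr.final_tokens.sum(axis=1) == 1)


def test_two_independent_transitions_split_binomially():
    # two separate self-sustaining loops; single-random picks one per step
    net = PetriNet(
        [Place("p0", initial_tokens=1), Place("p1", initial_tokens=1)],
        [Transition("t0"), Transition("t1")],
        [Arc("p0", "t0"), Arc("t0", "p0"), Arc("p1", "t1"), Arc("t1", "p1")],
    )
    cfg = SimulationConfig(steps=10_000, replicates=1, seed=11)
    tr = simulate(net, cfg)
    n0 = int(tr.firing_counts[0, 0])
    assert abs(n0 - 5000) <= 3 * 50  # binomial mean 5000, sd 50


def test_empty_knockout_compare_is_exactly_zero():
    for net in random_nets(4, ensure_covered=True):
        cfg = SimulationConfig(steps=50, replicates=3, seed=7)
        cmp = knockout_simulation_compare(net, cfg, [])
        assert all(v == 0.0 for v in cmp["firing_rate_diff"].values())
        assert all(v == 0.0 for v in cmp["final_tokens_diff"].values())


def test_knocking_the_cycle_head_silences_downstream():
    net = make_cycle_net(3)
    cfg = SimulationConfig(steps=100, replicates=2, seed=4)
    cmp = knockout_simulation_compare(net, cfg, ["t0"])
    # all transitions lose their entire firing rate
    assert all(v < 0 for v in cmp["firing_rate_diff"].values())
    assert cmp["knockout_stalls"] == 2


def test_branch_knockout_redirects_flow_toward_stationary_share():
    """Token chooses between two branches; knocking one doubles the other.

    With branches A and B from a single token pool, the single-random policy
    is an unbiased coin between the two enabled branch heads, so branch A
    fires ~half the steps; with B knocked the exact Markov chain has a single
    state whose only move is A, so A's rate tends to the whole step budget.
    """
    net = PetriNet(
        [Place("hub", initial_tokens=1)],
        [Transition("tA"), Transition("tB")],
        [Arc("hub", "tA"), Arc("tA", "hub"), Arc("hub", "tB"), Arc("tB", "hub")],
    )
    cfg = SimulationConfig(steps=4000, replicates=3, seed=13)
    cmp = knockout_simulation_compare(net, cfg, ["tB"])
    # control: rate(tA) ~ 0.5; knockout: rate(tA) = 1.0 -> diff ~ +0.5
    assert 0.45 < cmp["firing_rate_diff"]["tA"] < 0.55
    assert cmp["firing_rate_diff"]["tB"] < -0.45
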