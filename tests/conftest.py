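import pytest

from atheronet.net import Arc, PetriNet, Place, Transition
from atheronet.synth import GeneratorParams, make_cycle_net, make_random_net


@pytest.fixture
def cycle2():
    return make_cycle_net(2)


@pytest.fixture
def fork_net():
    """One transition consuming 1 of p0 and producing 2 of p1."""
    return PetriNet(
        [Place("p0", initial_tokens=1), Place("p1")],
        [Transition("t0")],
        [Arc("p0", "t0"), Arc("t0", "p1", 2)],
    )


def random_nets(n, *, max_weight=2, ensure_covered=False, start_seed=0):
    """Deterministic battery of small random nets for oracle comparisons."""
    rng_sizes = [(3, 4), (4, 5), (4, 6), (5, 7), (3, 6), (5, 5)]
    out = []
    for s in range(start_seed, start_seed + n):
        np_, nt = rng_sizes[s % len(rng_sizes)]
        out.append(make_random_net(GeneratorParams(
            n_places=np_, n_transitions=nt, density=0.35,
            max_weight=max_weight, seed=s, ensure_covered=ensure_covered)))
    return out
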