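"""Token-game simulation and the simulation-based knockout variant.

The simulator plays the standard firing rule: a transition is enabled when
every input place holds at least the arc weight; firing moves the weighted
token amounts. Two stochastic policies are provided:

``single-random``
    each step fires one transition chosen uniformly among the enabled ones;
``maximal-random``
    each step fires a maximal non-conflicting set, built by drawing enabled
    transitions in random order and keeping those still enabled after the
    tokens consumed so far.

Replicated runs from the same initial marking give firing-rate and token
distributions; the knockout variant compares a control arm against an arm
with chosen transitions disabled, using identical seeds so that a no-op
knockout gives exactly zero difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .net import Marking, PetriNet

__all__ = [
    "SimulationConfig",
    "SimulationTrace",
    "enabled_transitions",
    "fire",
    "simulate",
    "knockout_simulation_compare",
]


@dataclass(frozen=True)
class SimulationConfig:
    steps: int = 1000
    replicates: int = 100
    policy: str = "single-random"
    seed: int = 0
    disabled: frozenset[str] = frozenset()
    initial: Marking | None = None

    def __post_init__(self):
        if self.steps < 1 or self.replicates < 1:
            raise ValueError("steps and replicates must be >= 1")
        if self.policy not in ("single-random", "maximal-random"):
            raise ValueError(f"unknown firing policy: {self.policy!r}")


@dataclass
class SimulationTrace:
    transition_ids: list[str]
    place_ids: list[str]
    firing_counts: np.ndarray      # (replicates, transitions)
    final_tokens: np.ndarray       # (replicates, places)
    token_series: np.ndarray       # (series points, places) for replicate 0
    stalled_at: list[int | None]   # step at which each replicate stalled

    def firing_rates(self, steps: int) -> np.ndarray:
        return self.firing_counts / steps

    def summary(self) -> dict:
        return {
            "firing_rate_mean": {t: float(v) for t, v in
                                 zip(self.transition_ids, self.firing_counts.mean(0))},
            "firing_rate_sd": {t: float(v) for t, v in
                               zip(self.transition_ids, self.firing_counts.std(0, ddof=1)
                                   if len(self.firing_counts) > 1
                                   else np.zeros(len(self.transition_ids)))},
            "final_tokens_mean": {p: float(v) for p, v in
                                  zip(self.place_ids, self.final_tokens.mean(0))},
            "n_stalled": sum(1 for s in self.stalled_at if s is not None),
        }


def _io_tables(net: PetriNet):
    pidx = {p: i for i, p in enumerate(net.place_ids)}
    pre = {t: [] for t in net.transition_ids}
    post = {t: [] for t in net.transition_ids}
    for a in net.arcs:
        if a.target in pre:      # place -> transition
            pre[a.target].append((pidx[a.source], a.weight))
        else:                    # transition -> place
            post[a.source].append((pidx[a.target], a.weight))
    return pidx, pre, post


def enabled_transitions(net: PetriNet, marking: Marking) -> set[str]:
    """Transitions whose every input place holds at least the arc weight.

    A transition with no input places is always enabled (an input/source
    process).
    """
    _, pre, _ = _io_tables(net)
    tokens = marking.tokens
    out = set()
    pid = net.place_ids
    for t, ins in pre.items():
        if all(tokens.get(pid[i], 0) >= w for i, w in ins):
            out.add(t)
    return out


def fire(net: PetriNet, marking: Marking, tid: str) -> Marking:
    """Fire *tid*: decrement inputs, increment outputs. Errors if not enabled."""
    if tid not in set(net.transition_ids):
        raise KeyError(f"unknown transition: {tid}")
    if tid not in enabled_transitions(net, marking):
        raise ValueError(f"transition {tid} is not enabled at this marking")
    new = marking.copy()
    for a in net.arcs:
        if a.target == tid:
            new.tokens[a.source] = new.tokens.get(a.source, 0) - a.weight
        elif a.source == tid:
            new.tokens[a.target] = new.tokens.get(a.target, 0) + a.weight
    assert all(v >= 0 for v in new.tokens.values())
    return new


def simulate(net: PetriNet, config: SimulationConfig) -> SimulationTrace:
    """Run ``config.replicates`` independent token games of ``config.steps`` steps.

    Reproducible: replicate *r* uses a child generator of ``config.seed`` so
    the whole trace is a pure function of the configuration. A step with no
    enabled (non-disabled) transition stalls the replicate; stalls are data,
    not errors.
    """
    pidx, pre, post = _io_tables(net)
    tids = net.transition_ids
    pids = net.place_ids
    unknown = set(config.disabled) - set(tids)
    if unknown:
        raise KeyError(f"disabled set names unknown transitions: {sorted(unknown)}")
    init = config.initial if config.initial is not None else net.initial_marking()
    state0 = np.zeros(len(pids), dtype=np.int64)
    for p, v in init.tokens.items():
        state0[pidx[p]] = v

    active = [t for t in tids if t not in config.disabled]
    tindex = {t: j for j, t in enumerate(tids)}
    firing = np.zeros((config.replicates, len(tids)), dtype=np.int64)
    finals = np.zeros((config.replicates, len(pids)), dtype=np.int64)
    stalled: list[int | None] = []
    series: list[np.ndarray] = []
    sample_every = max(1, config.steps // 200)

    root = np.random.default_rng(config.seed)
    child_seeds = root.integers(0, 2**31 - 1, size=config.replicates)
    for r in range(config.replicates):
        rng = np.random.default_rng(int(child_seeds[r]))
        state = state0.copy()
        stall = None
        for step in range(config.steps):
            en = [t for t in active
                  if all(state[i] >= w for i, w in pre[t])]
            if not en:
                stall = step
                break
            if config.policy == "single-random":
                chosen = [en[rng.integers(len(en))]]
            else:
                order = rng.permutation(len(en))
                chosen = []
                tmp = state.copy()
                for k in order:
                    t = en[k]
                    if all(tmp[i] >= w for i, w in pre[t]):
                        for i, w in pre[t]:
                            tmp[i] -= w
                        chosen.append(t)
            for t in chosen:
                for i, w in pre[t]:
                    state[i] -= w
                for i, w in post[t]:
                    state[i] += w
                firing[r, tindex[t]] += 1
            if r == 0 and step % sample_every == 0:
                series.append(state.copy())
        assert np.all(state >= 0)
        finals[r] = state
        stalled.append(stall)
    return SimulationTrace(list(tids), list(pids), firing, finals,
                           np.array(series) if series else np.zeros((0, len(pids)), dtype=np.int64),
                           stalled)


def knockout_simulation_compare(net: PetriNet, base: SimulationConfig,
                                knocked: Iterable[str]) -> dict:
    """Control vs knockout arm with identical seeds/steps/replicates.

    Returns per-transition firing-rate differences and per-place final-token
    differences (knockout minus control) with across-replicate dispersion.
    An empty knockout gives exactly zero everywhere.
    """
    knocked = frozenset(knocked)
    control = simulate(net, base)
    ko_cfg = SimulationConfig(base.steps, base.replicates, base.policy, base.seed,
                              base.disabled | knocked, base.initial)
    ko = simulate(net, ko_cfg)
    dr = (ko.firing_counts - control.firing_counts) / base.steps
    dt = ko.final_tokens.astype(float) - control.final_tokens.astype(float)
    n = base.replicates
    sd = lambda x: x.std(0, ddof=1) if n > 1 else np.zeros(x.shape[1])
    return {
        "knocked": sorted(knocked),
        "firing_rate_diff": {t: float(v) for t, v in zip(net.transition_ids, dr.mean(0))},
        "firing_rate_diff_sd": {t: float(v) for t, v in zip(net.transition_ids, sd(dr))},
        "final_tokens_diff": {p: float(v) for p, v in zip(net.place_ids, dt.mean(0))},
        "final_tokens_diff_sd": {p: float(v) for p, v in zip(net.place_ids, sd(dt))},
        "control_stalls": sum(1 for s in control.stalled_at if s is not None),
        "knockout_stalls": sum(1 for s in ko.stalled_at if s is not None),
    }
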