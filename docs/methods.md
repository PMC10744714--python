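# Methods

## The model class

The package analyses qualitative place/transition Petri nets. Places stand
for passive components of a signalling or metabolic system (metabolites,
enzymes, complexes, cell states), transitions for elementary processes, and
weighted arcs for their causal coupling; a marking assigns a token count to
every place. The net structure is summarised by the incidence matrix
`A ∈ Z^{n×m}` (n places, m transitions) with `a_ij` the net token change on
place `p_i` when `t_j` fires. No kinetic parameters enter anywhere: every
result is a function of `A` alone, except for the token-game simulator,
which additionally needs an initial marking.

## Minimal t-invariants

A t-invariant is a vector `x ∈ Z^m`, `x ≥ 0`, `x ≠ 0`, with `A·x = 0`;
firing each transition of its support `s(x) = {t_j : x_j > 0}` the indicated
number of times leaves the marking unchanged, so invariants are read as
stationary subprocesses. "Minimal" is implemented as support-minimal with
the nonzero entries reduced to gcd 1. The enumeration is the classical
Farkas / Fourier–Motzkin scheme: starting from `[I | Aᵀ]`, places are
eliminated one at a time by combining rows of opposite sign in the place
column, reducing each combination by its gcd, and discarding rows whose
support strictly contains another row's. The elimination order is chosen
greedily by the product (positive rows × negative rows), the standard
heuristic against intermediate blow-up; the result is provably independent
of that order, and a test permutes transitions to confirm equivariance.
Arithmetic is int64 with explicit overflow guards, and a configurable cap on
intermediate rows turns pathological instances into a clean error instead of
memory exhaustion. Every returned vector is re-checked (`A·x = 0` asserted)
before it leaves the engine.

The independent oracle used in the test-suite enumerates all vectors in
`{0..bound}^m` directly (vectorised, default bound 6) and applies the same
canonicalisation. For unit- and small-weight nets of the tested sizes the
minimal invariants have entries well inside the bound, so engine and oracle
must agree exactly; the suite runs the comparison on 100 seeded random nets.

## MCT sets

Transitions are grouped by their signature — the set of invariants whose
supports contain them. Classes of this equivalence relation are the maximal
common transition (MCT) sets; classes of size > 1 are the non-trivial sets,
interpreted as functional modules. Labelling is deterministic: non-trivial
sets ordered by (size descending, smallest member index ascending) become
m1, m2, …; singletons are labelled by their transition. Knocking out any
member of an MCT set destroys exactly the invariants containing the whole
set, so member-level and set-level knockouts coincide; this is asserted on
random nets and on the curated model.

## Knockout analysis

For a knock-set `K`, the affected invariants are those whose support meets
`K`; the remaining invariants are the complement. A transition is *affected*
when it occurs in no remaining support. Impact is reported as the
percentage of affected transitions over all `m = 78` transitions (two
decimals, half-up), in two conventions: including the knocked transitions
themselves, and excluding them. For therapy scenarios the additional
statistic is the number of remaining invariants whose support contains the
target transition t43 ("atherosclerosis progression"): a blockade that
drives this from 90 to 0 halts progression in the modelled system.

## Token-game simulation

The simulator implements the standard enabling/firing rule. Two policies:
`single-random` fires one uniformly chosen enabled transition per step;
`maximal-random` fires a maximal non-conflicting set assembled in random
order. Defaults are 1000 steps × 100 replicates, single-random; the choice
is visible in `SimulationConfig` and logged in exports. Replicate r draws
its generator from a child seed of the configured seed, so traces are exact
functions of the configuration; the knockout comparison reuses the same
seeds in both arms, which makes the empty knockout an exact zero. A step
with no enabled transition stalls the replicate; stalls are recorded data.
The curated model ships without an initial marking (none is published), so
every simulation of it requires an explicit marking; the analysis script
seeds input-like places (places with no producing transition) with two
tokens as a documented, arbitrary convention. Simulation results are
therefore marking-dependent illustrations, not validated quantities — the
invariant-based results are the package's substantive output.

## The curated disease model

`data/curated_model.json` encodes the 66-place / 78-transition network
linking carbohydrate-metabolism disorder to atherosclerosis: glucose uptake
and glycolysis, the polyol, hexosamine-adjacent, PKC(β/γ), AGE–RAGE and
mitochondrial-ROS branches, antioxidant defense, and the endothelial-damage
cascade ending in plaque progression. The published figure of the network is
not machine-readable, and the node name lists are only partially recoverable
from the running text, so the shipped wiring is a *reconstruction*: the
printed structural results — 150 minimal t-invariants covering the net, 90
containing t43, the ten MCT memberships, the seven scenario outcomes, and
the single-transition impact percentages — were treated as a constraint
system, and a wiring satisfying all of them simultaneously was sought with a
combination of structural analysis and discrete local search. Two modelling
features of the reconstruction deserve note. First, several transitions are
synchronisations with two input and/or two output places; these let one
stationary subprocess require both a damage signal and a committed
signalling state, which is how the t43-invariants come to depend on the PKC
branch. Second, some places are catalytic side conditions — enzyme places
connected to a single transition by a read-arc pair. They contribute a zero
row to the incidence matrix, so they change no invariant, MCT or knockout
result, but they belong to the place inventory and matter for token-game
simulation (an unmarked enzyme silences its reaction). These
constraints over-determine the cycle structure tightly; the validation
checklist (`validate_reference_results`) recomputes every one of them from
the shipped file, and the model is shipped only in a state where all
enforced checks pass. Names attached to nodes follow the published
pathway narrative where ids are fixed by it (t43 atherosclerosis
progression, t32 aldose reductase, t55/t58 PKC expression/activation, t63
MGO formation, t34/t62 oxidases, t7 ROS+NO, t50/t77 NADPH/NADP cycling, t38
AGE–RAGE ROS) and are descriptive placeholders elsewhere. Where the
published record is internally inconsistent — impact percentages printed for
m3, m5 and m10 that are smaller than the sets themselves, and one scenario's
disabled-transition list that contradicts the MCT-equivalence property the
text itself states — the reconstruction follows the arithmetic-consistent
reading, and the inconsistent comparisons are carried as flagged,
non-enforced rows in the checklist and reports rather than being matched or
silently dropped. The same applies to place p28, which the published
narrative calls sorbitol in one scenario and MGO in another: the shipped
model names it sorbitol and records the ambiguity here.

## Synthetic nets

`make_cycle_net(k)` builds the alternating place/transition cycle (one
all-ones invariant, one MCT set). `make_random_net` samples a bipartite net
with configurable density and arc weights; bipartiteness holds by
construction. With `ensure_covered`, unit-weight cycles are threaded through
uncovered transitions until the net is covered by t-invariants, so the
repaired generator produces structures on which coverage-dependent
operations are exercised honestly. Generated nets emulate the structural
features the engines care about (cycles, shared transitions, weights); they
do not emulate biological semantics, so passing the random-net batteries
shows algorithmic correctness, not anything about disease biology.

## Numerical and design choices

- Percentages: decimal half-up to two places, matching the reporting
  convention of the reference tables (`percent(54, 78) = 69.23`).
- Invariant output order: lexicographic by sorted support indices, so
  exports are diffable.
- Test battery sizes (100 random nets for oracle equivalence, 20–50 for
  property checks, oracle bound 6) keep the default suite in the
  minutes range on one CPU while covering the size regime where the oracle
  is exact.
- The acceptance script derives all stochastic seeds from `--seed` and
  computes every reported number from the shipped model at run time.

## Known limitations

- The reconstruction is structurally faithful to every printed quantitative
  constraint, but arc-level identity with the unpublished figure cannot be
  verified; biological names off the constrained set are interpretive.
- Qualitative Petri nets ignore kinetics; knockout conclusions are
  statements about stationary subprocess structure, not about rates.
- The simulator's results depend on the user-supplied marking; no marking
  is part of the validated model.
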