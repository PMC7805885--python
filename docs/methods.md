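# Methods

## Model

Two players repeatedly play a prisoner's dilemma (T = 3, R = 2, P = 1,
S = 0). After each round the encounter continues with probability `n`
(expected length 1/(1 − n), so `n = 0.95` means twenty rounds on average).
Each round, each player's intended action is flipped with the execution
error probability `a`, independently across players and rounds. Errors
apply to cooperate/defect actions only; the reliability of apology is
modeled separately by `p` below.

Strategies are C (always cooperate), D (always defect), GT (grim trigger),
GP (guilt-prone grim trigger) and F (faker). GT and GP carry one bit of
within-encounter state — COOPERATIVE or PUNISHING — which is all the history
they condition on; PUNISHING is absorbing. Conditional strategies start
COOPERATIVE.

Apology works as follows. At the end of a round, GP and F apologize after
their own *realized* defections; GP pays `c` per apology, F pays `d`. A GP
apology is always believed (guilt acts as its own, honest signal); an F
apology is believed with probability `p`, drawn independently per apology
event. A GP whose partner defected does not turn punitive if it believed the
partner's apology; otherwise it enters PUNISHING and never returns — one
disbelieved or missing apology ends forgiveness for the rest of the
encounter. GT ignores apologies entirely. Apology resolution happens at
end-of-round; mode updates take effect the following round. Simultaneous
accidental defection by two GPs leaves both cooperative: both apologize,
both believe.

### Apology-issuance conventions

The default rules take the strategy descriptions literally: both apologizing
types apologize after **every** realized defection, including GP's intended
punitive defections and F's defections against already-punishing partners.
This is deliberate and load-bearing. It makes the apology cost a genuine
commitment: a guilt-prone player locked in mutual punishment keeps paying
`c` per round, so expensive apology norms hurt the guilt-prone as well as
the fakers they deter. That tension is what produces an *interior* optimum
of the shared cost `c = d` for the evolution of guilt-proneness (0.4 at
p = 0.95, 0.2 at p = 0.9 on the default grid). Two restricted variants are
provided as switches on `ModelParams`:

- `GPApologyPolicy.IF_COOPERATIVE` — GP apologizes only for accidental
  (cooperative-mode) defections;
- `FakerApologyPolicy.IF_PARTNER_COOPERATED` — F apologizes only when the
  partner actually cooperated that round.

Under these variants GP's total apology spending is tiny (rate `a` per
round at most), so raising `c = d` punishes fakers almost exclusively and
the guilt-prone basin grows monotonically with cost over the default grid —
a qualitatively different regime worth knowing about when comparing
conventions.

The asymmetric-cost regime of interest is `d ≥ c` (fakers pay at least as
much, because their apologies are less convincing); constructing parameters
with `d < c` warns but does not fail.

## Exact payoffs

An encounter between two strategies is a time-homogeneous Markov chain over
the joint modes (at most 4 states; C, D and F contribute a single effective
mode). For each state the four realized-action combinations are enumerated
with their probabilities from `a`, along with the apology events they
trigger and the belief branch (probability `p`) for faker apologies. This
yields per-state expected per-round rewards `r` (stage payoff minus expected
apology cost), apology rates, and the transition matrix `T`.

The expected total payoff over a geometric-length encounter solves
`v = r + n T v`, i.e. `v = (I − nT)⁻¹ r`, evaluated at the initial state.
Treating `n` as a discount is mathematically identical to averaging over
Geometric(1 − n) encounter lengths; payoffs are expected *totals*, not
per-round averages — stability and replicator conclusions are invariant to
that positive rescaling. The system is never singular for `n < 1` (row
sums of `nT` are `n`). Analytic identities are asserted at 1e-9 absolute;
transition stochasticity at 1e-12.

The independent cross-check is a Monte-Carlo simulator that draws a
geometric length per encounter (capped at 10⁴ rounds; truncation error below
n^10000, negligible for n ≤ 0.99) and plays round by round from the same
behavioral rules, vectorized across encounters. An exhaustive rule-table
test pins the vectorized update to the scalar rule functions; an
oracle-equivalence test requires every analytic matrix entry to sit within
four standard errors of the simulation at 10⁵ encounters.

## Stability analysis

`is_ess` applies the standard conditions per invader T:
E(S,S) > E(T,S), or |E(S,S) − E(T,S)| ≤ tol with E(S,T) > E(T,T), with a
tie tolerance of 1e-9 to absorb exact float ties (e.g. GP versus GT at
c = 0, where the two behave identically against GT). Boundary searches
(minimum stabilizing cost over [0, 5]; minimum continuation probability over
[0, 0.9999]) first scan 26 coarse points to verify a single False→True
switch of the ESS indicator, then bisect to 1e-4; a non-monotone scan falls
back to a fine grid search and logs a warning. When the strategy is already
stable at the lower end of the range the search returns that endpoint, and
`nan` marks "no value in range".

## Replicator dynamics and basins

The discrete-time replicator map reweights shares by shifted fitness:
`f_i = Σ_j (A_ij + shift) x_j`, `x'_i = x_i f_i / Σ_k x_k f_k`, with
`shift = max(0, 1 − min(A))` so fitnesses are positive. Discrete
*trajectories* (unlike fixed points) depend on the shift, so the shift is
computed once per matrix and shared across all runs of an experiment; an
invariance test checks that the selected vertex almost never changes between
two shift values (≥ 98 of 100 seeded starts, exact agreement for
guilt-prone-bound starts — a handful of trajectories near basin boundaries
may legitimately flip under the altered step sizes).

Basins are estimated from initial states drawn uniformly on the simplex
(symmetric Dirichlet, concentration 1 — the neutral choice, recorded in
output metadata). Each trajectory runs until some strategy's share exceeds
0.999 (default) or 10⁶ iterations, vectorized with converged runs retired
from the batch. The attractor is the dominant strategy at threshold
crossing; runs hitting the iteration cap are reported as unresolved, never
dropped. Caveat of this classification: a trajectory can cross the
threshold near a vertex that is *not* stable (e.g. all-faker populations,
which defection invades only slowly) and be tallied there; at the default
parameters this affects at most ~1% of runs and does not touch the
guilt-prone fraction, but it is why small fractions occasionally appear for
non-ESS strategies. Fractions carry 95% Wilson intervals.

`optimal_cost` sweeps a shared-cost grid, estimates the {C, D, GP, F} basin
at each cost with per-cost child seeds spawned from one master seed, and
returns the cost with the largest guilt-prone fraction, breaking exact ties
toward the smaller cost (the conservative claim).

## Problem sizes

Unit and property tests use 10²–10⁴ simulated encounters or replicator
starts; the oracle-equivalence checks use 2×10⁴–10⁵ encounters per pair.
The optimal-cost sweeps use 10,000 starts per grid cost in the test suite
and 20,000 in `scripts/acceptance.py`: adjacent grid costs near the optimum
differ in guilt-prone basin fraction by only ~0.01, so a stable argmax needs
binomial noise well below that (SE ≈ 0.003 at 20,000). The full suite runs
in well under a minute; the acceptance script in a few seconds.

## What the generated data does and does not show

All inputs are generated internally: parameter sets, uniform simplex
populations, and seeded random draws for errors, beliefs and encounter
lengths. The model treats "guilt-prone" purely as a behavioral strategy —
apologize, pay, forgive — with no representation of emotion, learning,
partner recognition, population structure, mutation, or finite-population
drift. Passing tests therefore establish properties of this idealized
evolutionary model, not claims about human psychology; the model's value is
the set of conditionals it yields (longer interactions, harder-to-fake
guilt, and moderate costs favor guilty apology).

## Known limitations

- The replicator is the deterministic infinite-population dynamic;
  stochastic stability and finite-population (Moran) dynamics are out of
  scope.
- Basin fractions depend mildly on the convergence threshold and on the
  positivity shift through discretization, as discussed above; both are
  fixed and recorded.
- Grim forgiveness is one-shot-per-encounter by construction (no forgiveness
  counters); alternative forgiveness schedules are not modeled.
- The GT-included population {D, GT, GP} is available through the library
  (`estimate_basin` accepts any strategy list, as does the `strategies`
  field of the basin presets) but is not part of the headline basin
  analyses, which use {C, D, GP, F}.
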