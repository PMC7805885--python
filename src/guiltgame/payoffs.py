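"""Expected whole-encounter payoffs for every ordered strategy pair.

An encounter between two strategies is a time-homogeneous Markov chain over
the joint within-encounter modes of the two players (at most 4 states). Each
state carries an expected per-round reward for each player — the stage payoff
minus the expected apology cost — obtained by exhaustively enumerating the
four realized-action combinations, the apology events they trigger, and the
belief draw for faker apologies.

The expected total payoff over an encounter of geometric length (another
round with probability ``n``) is the solution of the linear system

    v = r + n T v

where ``r`` is the per-state reward vector and ``T`` the transition matrix;
the encounter value is ``v`` at the initial both-cooperative state. A
round-by-round Monte-Carlo simulator of the same behavioral rules serves as
an independent oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    Action,
    FakerApologyPolicy,
    GPApologyPolicy,
    Mode,
    ModelParams,
    ParameterError,
    Strategy,
    apology_believed,
    apology_issued,
    effective_modes,
    intended_action,
    stage_payoff,
    update_mode,
)

#: Cap on simulated rounds per encounter; the probability a geometric
#: encounter exceeds it is n**MAX_ROUNDS, negligible for n <= 0.99.
MAX_ROUNDS = 10_000


def expected_rounds(n: float) -> float:
    """Expected encounter length 1/(1-n) for continuation probability ``n``."""
    if not 0.0 <= n < 1.0:
        raise ParameterError(f"continuation probability n must be in [0, 1), got {n}")
    return 1.0 / (1.0 - n)


@dataclass(frozen=True)
class PairProcess:
    """The joint Markov chain of one encounter between two strategies.

    ``states`` are joint (mode1, mode2) pairs; ``rewards[k, i]`` is player
    ``i``'s expected per-round reward in state ``k`` (stage payoff minus
    expected apology cost); ``apology_rates[k, i]`` is the per-round
    probability that player ``i`` issues an apology in state ``k``;
    ``transition[k, l]`` the one-round transition probability.
    """

    strategies: tuple[Strategy, Strategy]
    states: tuple[tuple[Mode, Mode], ...]
    rewards: np.ndarray
    apology_rates: np.ndarray
    transition: np.ndarray
    initial: int = 0


def build_pair_process(s1: Strategy, s2: Strategy, params: ModelParams) -> PairProcess:
    """Enumerate the encounter chain for the ordered pair (s1, s2)."""
    states = tuple(product(effective_modes(s1), effective_modes(s2)))
    index = {st: k for k, st in enumerate(states)}
    k = len(states)
    rewards = np.zeros((k, 2))
    apology_rates = np.zeros((k, 2))
    transition = np.zeros((k, k))
    a, p = params.a, params.p
    gp_pol, f_pol = params.gp_apology_policy, params.faker_apology_policy
    cost1 = params.apology_cost(s1)
    cost2 = params.apology_cost(s2)

    for st, (m1, m2) in enumerate(states):
        i1 = intended_action(s1, m1)
        i2 = intended_action(s2, m2)
        for r1, q1 in ((i1, 1.0 - a), (i1.flipped(), a)):
            for r2, q2 in ((i2, 1.0 - a), (i2.flipped(), a)):
                prob = q1 * q2
                if prob == 0.0:
                    continue
                ap1 = apology_issued(s1, m1, r1, r2, gp_pol, f_pol)
                ap2 = apology_issued(s2, m2, r2, r1, gp_pol, f_pol)
                rewards[st, 0] += prob * (stage_payoff(r1, r2) - cost1 * ap1)
                rewards[st, 1] += prob * (stage_payoff(r2, r1) - cost2 * ap2)
                apology_rates[st, 0] += prob * ap1
                apology_rates[st, 1] += prob * ap2
                # Belief branches: only a faker's apology is uncertain.
                for b1, w1 in _belief_branches(s1, ap1, p):
                    for b2, w2 in _belief_branches(s2, ap2, p):
                        nm1 = update_mode(s1, m1, r2, ap2 and b2)
                        nm2 = update_mode(s2, m2, r1, ap1 and b1)
                        transition[st, index[(nm1, nm2)]] += prob * w1 * w2
    return PairProcess(
        strategies=(s1, s2),
        states=states,
        rewards=rewards,
        apology_rates=apology_rates,
        transition=transition,
    )


def _belief_branches(strategy: Strategy, issued: bool, p: float):
    if not issued or strategy is not Strategy.F:
        # GP apologies are always believed; absent apologies carry no draw.
        return ((issued, 1.0),)
    if p >= 1.0:
        return ((True, 1.0),)
    return ((True, p), (False, 1.0 - p))


def _solve_geometric(process: PairProcess, n: float, per_state: np.ndarray) -> np.ndarray:
    """Solve v = per_state + n T v and return v at the initial state (per player)."""
    if not 0.0 <= n < 1.0:
        raise ParameterError(f"continuation probability n must be in [0, 1), got {n}")
    k = len(process.states)
    system = np.eye(k) - n * process.transition
    v = np.linalg.solve(system, per_state)
    return v[process.initial]


def expected_pair_payoffs(process: PairProcess, n: float) -> tuple[float, float]:
    """Exact expected total payoffs (player 1, player 2) for one encounter.

    Equivalently: the expectation of the summed per-round payoffs over an
    encounter whose length is Geometric(1-n).
    """
    v = _solve_geometric(process, n, process.rewards)
    return float(v[0]), float(v[1])


def expected_apologies(process: PairProcess, n: float) -> tuple[float, float]:
    """Expected number of apologies each player issues over one encounter."""
    v = _solve_geometric(process, n, process.apology_rates)
    return float(v[0]), float(v[1])


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------


def _intends_defect(s: Strategy, punishing: np.ndarray) -> np.ndarray:
    if s is Strategy.C:
        return np.zeros_like(punishing)
    if s in (Strategy.D, Strategy.F):
        return np.ones_like(punishing)
    return punishing.copy()


def _issues_apology(
    s: Strategy,
    punishing: np.ndarray,
    own_defected: np.ndarray,
    partner_defected: np.ndarray,
    gp_policy: GPApologyPolicy,
    faker_policy: FakerApologyPolicy,
) -> np.ndarray:
    if s is Strategy.GP:
        if gp_policy is GPApologyPolicy.ALWAYS:
            return own_defected.copy()
        return own_defected & ~punishing
    if s is Strategy.F:
        if faker_policy is FakerApologyPolicy.ALWAYS:
            return own_defected.copy()
        return own_defected & ~partner_defected
    return np.zeros_like(own_defected)


def _next_punishing(
    s: Strategy,
    punishing: np.ndarray,
    partner_defected: np.ndarray,
    believed_apology: np.ndarray,
) -> np.ndarray:
    if s is Strategy.GT:
        return punishing | partner_defected
    if s is Strategy.GP:
        return punishing | (partner_defected & ~believed_apology)
    return punishing


def simulate_encounters(
    s1: Strategy,
    s2: Strategy,
    params: ModelParams,
    reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``reps`` independent encounters; return per-encounter totals.

    Vectorized across encounters: each round draws execution errors and
    faker-belief outcomes for all still-active encounters and applies the
    same behavioral rules as :mod:`guiltgame.model`.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if params.n > 0:
        lengths = np.minimum(rng.geometric(1.0 - params.n, size=reps), MAX_ROUNDS)
    else:
        lengths = np.ones(reps, dtype=np.int64)
    total1 = np.zeros(reps)
    total2 = np.zeros(reps)
    pun1 = np.zeros(reps, dtype=bool)
    pun2 = np.zeros(reps, dtype=bool)
    cost1 = params.apology_cost(s1)
    cost2 = params.apology_cost(s2)
    gp_pol, f_pol = params.gp_apology_policy, params.faker_apology_policy
    a, p = params.a, params.p

    active = np.arange(reps)
    for t in range(1, int(lengths.max()) + 1):
        still = lengths[active] >= t
        active = active[still]
        if active.size == 0:
            break
        m = active.size
        ap1 = pun1[active]
        ap2 = pun2[active]
        d1 = _intends_defect(s1, ap1) ^ (rng.random(m) < a)
        d2 = _intends_defect(s2, ap2) ^ (rng.random(m) < a)
        pay1 = np.where(d1, np.where(d2, 1.0, 3.0), np.where(d2, 0.0, 2.0))
        pay2 = np.where(d2, np.where(d1, 1.0, 3.0), np.where(d1, 0.0, 2.0))
        apol1 = _issues_apology(s1, ap1, d1, d2, gp_pol, f_pol)
        apol2 = _issues_apology(s2, ap2, d2, d1, gp_pol, f_pol)
        bel1 = apol1 & ((rng.random(m) < p) if s1 is Strategy.F else True)
        bel2 = apol2 & ((rng.random(m) < p) if s2 is Strategy.F else True)
        total1[active] += pay1 - cost1 * apol1
        total2[active] += pay2 - cost2 * apol2
        pun1[active] = _next_punishing(s1, ap1, d2, bel2)
        pun2[active] = _next_punishing(s2, ap2, d1, bel1)
    return total1, total2


def mc_pair_payoffs(
    s1: Strategy,
    s2: Strategy,
    params: ModelParams,
    reps: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Monte-Carlo estimate of the pair payoffs: ((mean1, se1), (mean2, se2))."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total1, total2 = simulate_encounters(s1, s2, params, reps, rng)
    se = lambda x: float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")
    return (float(total1.mean()), se(total1)), (float(total2.mean()), se(total2))


# ---------------------------------------------------------------------------
# Payoff matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PayoffMatrix:
    """Expected whole-encounter payoffs for every ordered strategy pair.

    ``values[i, j]`` is the expected total payoff to a row-``i`` player in an
    encounter with a column-``j`` player.
    """

    strategies: tuple[Strategy, ...]
    values: np.ndarray
    params: ModelParams

    def value(self, row: Strategy, col: Strategy) -> float:
        i = self.strategies.index(row)
        j = self.strategies.index(col)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        labels = [s.value for s in self.strategies]
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="strategy")

    def to_json(self, path=None):
        payload = {
            "params": self.params.to_dict(),
            "strategies": [s.value for s in self.strategies],
            "values": self.values.tolist(),
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return None


def build_payoff_matrix(
    strategies: Sequence[Strategy],
    params: ModelParams,
) -> PayoffMatrix:
    """Exact expected-payoff matrix over the given (duplicate-free) strategies."""
    strategies = tuple(strategies)
    if len(set(strategies)) != len(strategies):
        raise ValueError("duplicate strategies in payoff matrix request")
    k = len(strategies)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            process = build_pair_process(strategies[i], strategies[j], params)
            v1, v2 = expected_pair_payoffs(process, params.n)
            values[i, j] = v1
            values[j, i] = v2
    return PayoffMatrix(strategies=strategies, values=values, params=params)
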