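"""ESS certification, stability-boundary searches, replicator dynamics, basins.

A strategy S is evolutionarily stable against an invader T when
E(S,S) > E(T,S), or E(S,S) = E(T,S) and E(S,T) > E(T,T) (Maynard Smith
conditions, with a floating-point tie tolerance). Boundary searches locate
the smallest apology cost (or continuation probability) at which the
guilt-prone strategy becomes an ESS, by bisection on a scan-verified
monotone margin.

Population change follows the discrete-time replicator dynamics

    x'_i = x_i * f_i / sum_k x_k f_k,    f_i = sum_j (A_ij + shift) x_j,

with a uniform positivity shift so that fitnesses are positive. Basins of
attraction are estimated by sampling initial populations uniformly from the
simplex and iterating each trajectory until one strategy's share exceeds a
convergence threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import ModelParams, Strategy
from .payoffs import PayoffMatrix, build_payoff_matrix

logger = logging.getLogger(__name__)

#: z for 95% binomial (Wilson) intervals on basin fractions.
_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# ESS certification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ESSReport:
    """Per-invader Maynard-Smith conditions for one resident strategy."""

    strategy: Strategy
    invaders: tuple[Strategy, ...]
    is_ess: bool
    #: invader -> (E(S,S) - E(T,S), E(S,T) - E(T,T))
    margins: dict
    conditions: dict
    tolerance: float

    def __str__(self) -> str:
        lines = [f"ESS report for {self.strategy}: {'ESS' if self.is_ess else 'not ESS'}"]
        for t in self.invaders:
            m1, m2 = self.margins[t]
            lines.append(
                f"  vs {t!s:>2}: self-play margin {m1:+.6g}, "
                f"tie-break margin {m2:+.6g} -> {'ok' if self.conditions[t] else 'invadable'}"
            )
        return "\n".join(lines)


def is_ess(
    strategy: Strategy,
    invaders: Sequence[Strategy],
    matrix: PayoffMatrix,
    tolerance: float = 1e-9,
) -> ESSReport:
    """Certify ``strategy`` as an ESS against each invader using ``matrix``."""
    if strategy not in matrix.strategies:
        raise ValueError(f"{strategy} not in payoff matrix")
    margins = {}
    conditions = {}
    e_ss = matrix.value(strategy, strategy)
    for t in invaders:
        if t == strategy:
            continue
        if t not in matrix.strategies:
            raise ValueError(f"invader {t} not in payoff matrix")
        primary = e_ss - matrix.value(t, strategy)
        secondary = matrix.value(strategy, t) - matrix.value(t, t)
        if primary > tolerance:
            ok = True
        elif abs(primary) <= tolerance:
            ok = secondary > tolerance
        else:
            ok = False
        margins[t] = (primary, secondary)
        conditions[t] = ok
    invaders = tuple(margins)
    return ESSReport(
        strategy=strategy,
        invaders=invaders,
        is_ess=all(conditions.values()),
        margins=margins,
        conditions=conditions,
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# Stability-boundary searches
# ---------------------------------------------------------------------------


def _threshold_search(
    predicate: Callable[[float], bool],
    lo: float,
    hi: float,
    tol: float,
    scan_points: int,
) -> float:
    """Smallest x in [lo, hi] with predicate(x) True, assuming a single
    False->True switch; verified by coarse scan, with grid-search fallback.

    Returns ``nan`` when the predicate is False on the whole range.
    """
    grid = np.linspace(lo, hi, scan_points)
    flags = [predicate(float(x)) for x in grid]
    if not any(flags):
        return math.nan
    first_true = flags.index(True)
    monotone = all(flags[first_true:])
    if first_true == 0:
        return float(grid[0])
    if not monotone:
        logger.warning(
            "non-monotone stability margin on coarse scan; falling back to grid search"
        )
        fine = np.arange(lo, hi + tol, tol)
        for x in fine:
            if predicate(float(x)):
                return float(x)
        return math.nan
    a, b = float(grid[first_true - 1]), float(grid[first_true])
    while b - a > tol:
        mid = 0.5 * (a + b)
        if predicate(mid):
            b = mid
        else:
            a = mid
    return b


def min_cost_for_ess_vs_faker(
    p: float,
    n: float,
    a: float = 0.01,
    search_range: tuple[float, float] = (0.0, 5.0),
    tol: float = 1e-4,
    scan_points: int = 26,
    tolerance: float = 1e-9,
) -> float:
    """Smallest shared apology cost c = d making guilt-prone an ESS vs faker.

    Returns ``nan`` when no cost in the search range stabilizes guilt-prone.
    """

    def stable_at(cost: float) -> bool:
        params = ModelParams(n=n, a=a, p=p, c=cost, d=cost)
        matrix = build_payoff_matrix((Strategy.GP, Strategy.F), params)
        return is_ess(Strategy.GP, (Strategy.F,), matrix, tolerance).is_ess

    return _threshold_search(stable_at, *search_range, tol, scan_points)


def min_continuation_for_ess(
    invader: Strategy,
    c: float,
    a: float = 0.01,
    p: float = 0.95,
    search_range: tuple[float, float] = (0.0, 0.9999),
    tol: float = 1e-4,
    scan_points: int = 26,
    tolerance: float = 1e-9,
) -> float:
    """Smallest continuation probability n making guilt-prone an ESS vs invader.

    ``invader`` is one of C, D, GT (fakeability is irrelevant against them,
    but ``p`` is accepted for completeness). Returns ``nan`` if no n in range
    qualifies.
    """
    if invader not in (Strategy.C, Strategy.D, Strategy.GT):
        raise ValueError(f"invader must be C, D or GT, got {invader}")

    def stable_at(n: float) -> bool:
        params = ModelParams(n=n, a=a, p=p, c=c, d=c)
        matrix = build_payoff_matrix((Strategy.GP, invader), params)
        return is_ess(Strategy.GP, (invader,), matrix, tolerance).is_ess

    return _threshold_search(stable_at, *search_range, tol, scan_points)


# ---------------------------------------------------------------------------
# Replicator dynamics
# ---------------------------------------------------------------------------


def default_shift(values: np.ndarray) -> float:
    """Uniform payoff shift guaranteeing shifted payoffs >= 1."""
    return max(0.0, 1.0 - float(np.min(values)))


def replicator_step(x: np.ndarray, matrix: PayoffMatrix, shift: float) -> np.ndarray:
    """One discrete-time replicator update of the population state ``x``."""
    x = np.asarray(x, dtype=float)
    f = (matrix.values + shift) @ x
    xf = x * f
    total = xf.sum()
    if total <= 0.0:
        raise ValueError("non-positive mean fitness; increase the payoff shift")
    return xf / total


@dataclass(frozen=True)
class ReplicatorRun:
    attractor: Strategy | None  # None when unresolved at the iteration cap
    iterations: int
    final_state: np.ndarray


def run_replicator(
    x0: np.ndarray,
    matrix: PayoffMatrix,
    threshold: float = 0.999,
    max_iter: int = 1_000_000,
    shift: float | None = None,
) -> ReplicatorRun:
    """Iterate the replicator map until one strategy's share exceeds
    ``threshold``, classifying the trajectory by its dominant strategy."""
    x = np.asarray(x0, dtype=float)
    if x.min() < 0 or abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("x0 must be a probability vector over the strategy list")
    if shift is None:
        shift = default_shift(matrix.values)
    for it in range(max_iter + 1):
        j = int(np.argmax(x))
        if x[j] > threshold:
            return ReplicatorRun(matrix.strategies[j], it, x)
        if it == max_iter:
            break
        x = replicator_step(x, matrix, shift)
    return ReplicatorRun(None, max_iter, x)


def _run_replicator_batch(
    x0: np.ndarray,
    matrix: PayoffMatrix,
    threshold: float,
    max_iter: int,
    shift: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized replicator runs: returns (attractor index or -1, iterations).

    Converged trajectories are retired from the active set as they finish.
    """
    x = np.array(x0, dtype=float)
    n_runs = x.shape[0]
    shifted = matrix.values + shift
    attractor = np.full(n_runs, -1, dtype=int)
    iterations = np.zeros(n_runs, dtype=np.int64)
    active = np.arange(n_runs)
    for it in range(max_iter + 1):
        j = np.argmax(x, axis=1)
        done = x[np.arange(x.shape[0]), j] > threshold
        if done.any():
            idx = active[done]
            attractor[idx] = j[done]
            iterations[idx] = it
            keep = ~done
            active = active[keep]
            x = x[keep]
        if active.size == 0 or it == max_iter:
            iterations[active] = max_iter
            break
        f = x @ shifted.T
        xf = x * f
        x = xf / xf.sum(axis=1, keepdims=True)
    return attractor, iterations


# ---------------------------------------------------------------------------
# Basin estimation
# ---------------------------------------------------------------------------


def _wilson_interval(successes: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    phat = successes / n
    z2 = _Z95**2
    denom = 1.0 + z2 / n
    center = (phat + z2 / (2 * n)) / denom
    half = _Z95 * math.sqrt(phat * (1 - phat) / n + z2 / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


@dataclass(frozen=True)
class BasinEstimate:
    """Fractions of uniformly sampled initial populations converging to each
    terminal rest point, with 95% Wilson intervals."""

    strategies: tuple[Strategy, ...]
    params: ModelParams
    attractor_fractions: dict
    intervals: dict
    samples: int
    unresolved: int
    seed: int | None
    shift: float

    def fraction(self, strategy: Strategy) -> float:
        return self.attractor_fractions.get(strategy, 0.0)


def estimate_basin(
    params: ModelParams,
    strategies: Sequence[Strategy],
    samples: int = 1000,
    seed: int | np.random.Generator = 0,
    threshold: float = 0.999,
    max_iter: int = 1_000_000,
    matrix: PayoffMatrix | None = None,
) -> BasinEstimate:
    """Estimate basins of attraction under the discrete replicator dynamics.

    Initial states are drawn uniformly from the simplex (symmetric Dirichlet
    with unit concentration). Trajectories that never reach the dominance
    threshold within ``max_iter`` are counted as unresolved, never dropped.
    """
    if samples < 1:
        raise ValueError("samples must be >= 1")
    strategies = tuple(strategies)
    if matrix is None:
        matrix = build_payoff_matrix(strategies, params)
    elif matrix.strategies != strategies:
        raise ValueError("matrix strategies do not match requested strategy list")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x0 = rng.dirichlet(np.ones(len(strategies)), size=samples)
    shift = default_shift(matrix.values)
    attractor, _ = _run_replicator_batch(x0, matrix, threshold, max_iter, shift)
    fractions = {}
    intervals = {}
    for i, s in enumerate(strategies):
        count = int((attractor == i).sum())
        if count:
            fractions[s] = count / samples
            intervals[s] = _wilson_interval(count, samples)
    unresolved = int((attractor == -1).sum())
    return BasinEstimate(
        strategies=strategies,
        params=params,
        attractor_fractions=fractions,
        intervals=intervals,
        samples=samples,
        unresolved=unresolved,
        seed=seed if isinstance(seed, int) else None,
        shift=shift,
    )


# ---------------------------------------------------------------------------
# Optimal apology cost
# ---------------------------------------------------------------------------

#: The strategy set of the headline basin analyses.
BASIN_STRATEGIES = (Strategy.C, Strategy.D, Strategy.GP, Strategy.F)


@dataclass(frozen=True)
class OptimalCostResult:
    best_cost: float
    gp_fractions: dict  # cost -> GP basin fraction
    estimates: dict  # cost -> BasinEstimate
    samples: int
    seed: int


def optimal_cost(
    p: float,
    cost_grid: Sequence[float],
    params_base: ModelParams | None = None,
    samples: int = 1000,
    seed: int = 0,
    strategies: Sequence[Strategy] = BASIN_STRATEGIES,
) -> OptimalCostResult:
    """The grid cost c = d maximizing the guilt-prone basin of attraction.

    Ties (within exact equality of fractions) break toward the smaller cost.
    """
    cost_grid = [float(c) for c in cost_grid]
    if not cost_grid:
        raise ValueError("cost grid must be non-empty")
    if params_base is None:
        params_base = ModelParams(p=p)
    child_seeds = np.random.SeedSequence(seed).spawn(len(cost_grid))
    estimates = {}
    fractions = {}
    for cost, child in zip(cost_grid, child_seeds):
        params = params_base.replace(p=p, c=cost, d=cost)
        est = estimate_basin(
            params, strategies, samples=samples, seed=np.random.default_rng(child)
        )
        estimates[cost] = est
        fractions[cost] = est.fraction(Strategy.GP)
        logger.info("cost %.3f: GP basin fraction %.4f", cost, fractions[cost])
    best = max(sorted(fractions), key=lambda c: fractions[c])
    # max() with sorted keys already breaks ties toward the smaller cost
    return OptimalCostResult(
        best_cost=best,
        gp_fractions=fractions,
        estimates=estimates,
        samples=samples,
        seed=seed,
    )
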