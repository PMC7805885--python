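"""Reproducible experiment presets with CSV output and JSON metadata.

Presets:

``ess-cost``
    Minimum shared apology cost c = d for guilt-prone to be an ESS against
    the faker, swept over fakeability p for several continuation
    probabilities n.
``ess-continuation``
    Minimum continuation probability n for guilt-prone to be an ESS against
    each of C, D and GT, swept over the apology cost c.
``basin-cost``
    Guilt-prone basin of attraction (strategies C, D, GP, F) as the shared
    cost c = d sweeps a grid, for several fakeability values p.
``basin-faker-cost``
    Guilt-prone basin of attraction as the faker's cost d sweeps upward while
    the guilt-prone cost c is held fixed (asymmetric-cost regime d >= c).

Every CSV row carries the complete parameter set, seed and sample count, so
any row can be recomputed from its own metadata. Output is deterministic for
a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .model import FakerApologyPolicy, GPApologyPolicy, ModelParams, Strategy
from .evolution import (
    BASIN_STRATEGIES,
    estimate_basin,
    min_continuation_for_ess,
    min_cost_for_ess_vs_faker,
)

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "experiment",
    "n",
    "a",
    "p",
    "c",
    "d",
    "strategy_set",
    "samples",
    "seed",
    "metric_name",
    "value",
    "ci_low",
    "ci_high",
]

PRESETS = ("ess-cost", "ess-continuation", "basin-cost", "basin-faker-cost")

DEFAULT_COST_GRID = (0.005, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class ExperimentConfig:
    """Configuration of one experiment preset run."""

    experiment: str
    n_grid: Sequence[float] = (0.95,)
    a: float = 0.01
    p_grid: Sequence[float] = (0.1, 0.5, 0.9, 0.95)
    cost_grid: Sequence[float] = DEFAULT_COST_GRID
    d_grid: Sequence[float] | None = None
    invaders: Sequence[Strategy] = (Strategy.C, Strategy.D, Strategy.GT)
    strategies: Sequence[Strategy] = BASIN_STRATEGIES
    samples: int = 1000
    seed: int = 0
    gp_apology_policy: GPApologyPolicy = GPApologyPolicy.ALWAYS
    faker_apology_policy: FakerApologyPolicy = FakerApologyPolicy.ALWAYS
    output: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in PRESETS:
            raise ValueError(f"unknown preset {self.experiment!r}; choose from {PRESETS}")
        for name, grid in (("n_grid", self.n_grid), ("p_grid", self.p_grid),
                           ("cost_grid", self.cost_grid)):
            if len(list(grid)) == 0:
                raise ValueError(f"{name} must be non-empty")
        # Validate every grid point against the parameter constraints.
        for n in self.n_grid:
            ModelParams(n=n, a=self.a)
        for p in self.p_grid:
            ModelParams(p=p, a=self.a)
        for cost in self.cost_grid:
            ModelParams(c=cost, d=cost, a=self.a)


def _row(experiment, params: ModelParams, strategy_set, samples, seed, metric, value,
         ci=(float("nan"), float("nan"))):
    return {
        "experiment": experiment,
        "n": params.n,
        "a": params.a,
        "p": params.p,
        "c": params.c,
        "d": params.d,
        "strategy_set": "+".join(str(s) for s in strategy_set),
        "samples": samples,
        "seed": seed,
        "metric_name": metric,
        "value": value,
        "ci_low": ci[0],
        "ci_high": ci[1],
    }


def run_experiment(config: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    """Run a preset; return (result table, metadata). Writes CSV + JSON
    sidecar when ``config.output`` is set."""
    runner = {
        "ess-cost": _run_ess_cost,
        "ess-continuation": _run_ess_continuation,
        "basin-cost": _run_basin_cost,
        "basin-faker-cost": _run_basin_faker_cost,
    }[config.experiment]
    rows = runner(config)
    table = pd.DataFrame(rows, columns=CSV_COLUMNS)
    metadata = {
        "experiment": config.experiment,
        "version": __version__,
        "seed": config.seed,
        "samples": config.samples,
        "a": config.a,
        "gp_apology_policy": config.gp_apology_policy.value,
        "faker_apology_policy": config.faker_apology_policy.value,
        "rows": len(table),
    }
    if config.output:
        table.to_csv(config.output, index=False)
        with open(str(config.output) + ".meta.json", "w") as fh:
            json.dump(metadata, fh, indent=2)
        logger.info("wrote %d rows to %s", len(table), config.output)
    return table, metadata


def _run_ess_cost(config: ExperimentConfig):
    rows = []
    for n in config.n_grid:
        for p in config.p_grid:
            c_star = min_cost_for_ess_vs_faker(p=p, n=n, a=config.a)
            params = ModelParams(n=n, a=config.a, p=p,
                                 c=c_star if c_star == c_star else 0.0,
                                 d=c_star if c_star == c_star else 0.0)
            rows.append(_row("ess-cost", params, (Strategy.GP, Strategy.F),
                             0, config.seed, "min_cost_for_gp_ess_vs_faker", c_star))
            logger.info("ess-cost n=%.3f p=%.3f -> c*=%s", n, p, c_star)
    return rows


def _run_ess_continuation(config: ExperimentConfig):
    rows = []
    for invader in config.invaders:
        for cost in config.cost_grid:
            n_star = min_continuation_for_ess(invader, c=cost, a=config.a)
            params = ModelParams(n=n_star if n_star == n_star else 0.0,
                                 a=config.a, c=cost, d=cost)
            rows.append(_row("ess-continuation", params, (Strategy.GP, invader),
                             0, config.seed, f"min_n_for_gp_ess_vs_{invader}", n_star))
            logger.info("ess-continuation invader=%s c=%.3f -> n*=%s",
                        invader, cost, n_star)
    return rows


def _run_basin_cost(config: ExperimentConfig):
    rows = []
    n = config.n_grid[0]
    seeds = np.random.SeedSequence(config.seed).spawn(
        len(list(config.p_grid)) * len(list(config.cost_grid)))
    seed_iter = iter(seeds)
    for p in config.p_grid:
        for cost in config.cost_grid:
            params = ModelParams(n=n, a=config.a, p=p, c=cost, d=cost,
                                 gp_apology_policy=config.gp_apology_policy,
                                 faker_apology_policy=config.faker_apology_policy)
            est = estimate_basin(params, config.strategies, samples=config.samples,
                                 seed=np.random.default_rng(next(seed_iter)))
            frac = est.fraction(Strategy.GP)
            ci = est.intervals.get(Strategy.GP, (0.0, 0.0))
            rows.append(_row("basin-cost", params, config.strategies,
                             config.samples, config.seed,
                             "gp_basin_fraction", frac, ci))
            if est.unresolved:
                logger.info("basin-cost p=%.3f c=%.3f: %d unresolved runs",
                            p, cost, est.unresolved)
            logger.info("basin-cost p=%.3f c=%.3f -> GP basin %.4f", p, cost, frac)
    return rows


def _run_basin_faker_cost(config: ExperimentConfig):
    rows = []
    n = config.n_grid[0]
    p = config.p_grid[0] if len(list(config.p_grid)) == 1 else 0.95
    c_values = (0.0, 0.2)
    specs = []
    for c_fixed in c_values:
        d_grid = config.d_grid
        if d_grid is None:
            start = max(c_fixed + 0.01, 0.01)
            d_grid = [round(x, 3) for x in np.arange(start, 0.901, 0.1)]
        specs.extend((c_fixed, d) for d in d_grid)
    seeds = np.random.SeedSequence(config.seed).spawn(len(specs))
    for (c_fixed, d), child in zip(specs, seeds):
        params = ModelParams(n=n, a=config.a, p=p, c=c_fixed, d=d,
                             gp_apology_policy=config.gp_apology_policy,
                             faker_apology_policy=config.faker_apology_policy)
        est = estimate_basin(params, config.strategies, samples=config.samples,
                             seed=np.random.default_rng(child))
        frac = est.fraction(Strategy.GP)
        ci = est.intervals.get(Strategy.GP, (0.0, 0.0))
        rows.append(_row("basin-faker-cost", params, config.strategies,
                         config.samples, config.seed, "gp_basin_fraction", frac, ci))
        logger.info("basin-faker-cost c=%.2f d=%.2f -> GP basin %.4f", c_fixed, d, frac)
    return rows


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------


def plot_results(table: pd.DataFrame, preset: str, path=None):
    """Line plot of a preset's result table (cosmetic; nothing is asserted
    from the rendered figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(table) == 0:
        raise ValueError("empty result table")
    if "experiment" in table.columns and not (table["experiment"] == preset).all():
        raise ValueError(f"table does not come from preset {preset!r}")
    fig, ax = plt.subplots(figsize=(6, 4))
    if preset == "ess-cost":
        for n, sub in table.groupby("n"):
            ax.plot(sub["p"], sub["value"], marker="o", label=f"n = {n:g}")
        ax.set_xlabel("fakeability p")
        ax.set_ylabel("minimum cost c for GP to be an ESS vs F")
    elif preset == "ess-continuation":
        for metric, sub in table.groupby("metric_name"):
            ax.plot(sub["c"], sub["value"], marker="o",
                    label=metric.rsplit("_", 1)[-1])
        ax.set_xlabel("apology cost c")
        ax.set_ylabel("minimum n for GP to be an ESS")
    elif preset == "basin-cost":
        for p, sub in table.groupby("p"):
            ax.plot(sub["c"], sub["value"], marker="o", label=f"p = {p:g}")
        ax.set_xlabel("apology cost c = d")
        ax.set_ylabel("GP basin of attraction")
    elif preset == "basin-faker-cost":
        for c, sub in table.groupby("c"):
            ax.plot(sub["d"], sub["value"], marker="o", label=f"c = {c:g}")
        ax.set_xlabel("faker apology cost d")
        ax.set_ylabel("GP basin of attraction")
    else:
        raise ValueError(f"unknown preset {preset!r}")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
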