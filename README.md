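# guiltgame

Evolutionary dynamics of guilty apology in a noisy iterated prisoner's
dilemma.

When partners interact repeatedly and sometimes err — defecting by accident —
strictly reciprocal strategies like the grim trigger destroy long, mutually
profitable relationships over honest mistakes. A *guilt-prone* strategy that
apologizes after its own defections, and forgives partners whose apologies it
believes, can recover those relationships. But forgiveness invites *fakers*
who apologize while intending to keep defecting. This package computes when
guilt-prone behavior is evolutionarily stable, and how likely it is to
evolve, as a function of how long interactions last, how hard guilt is to
fake, and what an apology costs. It is aimed at researchers in evolutionary
game theory and at emotion researchers who want quantitative conditionals of
the form "if interactions are long and guilt is hard to fake, guilty apology
is favored".

## The model

Two players repeatedly play a prisoner's dilemma with stage payoffs
T = 3 (defect on a cooperator), R = 2 (mutual cooperation), P = 1 (mutual
defection), S = 0 (cooperate with a defector). After every round the
encounter continues with probability *n*, so its expected length is
1/(1 − n). Each round an execution error flips a player's intended action
with probability *a*. The strategy set is

| id | behavior |
|----|----------|
| C  | always cooperate |
| D  | always defect |
| GT | grim trigger: cooperate until the partner defects once, then defect forever |
| GP | guilt-prone grim trigger: grim trigger that apologizes (cost *c*) after its own defections and forgives partners whose apologies it believes |
| F  | faker: always defect, apologize (cost *d*) after defecting |

A guilt-prone apology is always believed; a faker's apology is believed with
probability *p* ("fakeability"). Apologies are issued after every realized
defection (restricted variants are available as configuration switches).

Each ordered pair of strategies defines a Markov chain over the players'
joint punishment modes (at most 4 states). The expected whole-encounter
payoff is the exact solution of `v = r + n T v`, where `r` holds per-round
expected rewards (stage payoff minus expected apology cost) and `T` the
transition matrix; a vectorized round-by-round Monte-Carlo simulator serves
as an independent cross-check. On top of the payoff matrix the package
certifies evolutionarily stable strategies (E(S,S) > E(T,S), or equality
with E(S,T) > E(T,T)), locates stability boundaries by bisection, and
estimates basins of attraction under the discrete-time replicator dynamics
`x'_i = x_i f_i / Σ_k x_k f_k` from initial populations drawn uniformly from
the simplex.

## Worked example

Expected whole-encounter payoffs at the headline parameters — long
encounters (n = 0.95, twenty rounds on average), rare errors (a = 0.01),
very convincing fakers (p = 0.95), symmetric apology cost c = d = 0.4:

```
$ guiltgame payoffs -n 0.95 -a 0.01 -p 0.95 -c 0.4
expected rounds per encounter: 20
          C        D       GT       GP        F
C   39.8000   0.6000  33.5412  33.5412   0.6000
D   59.4000  20.2000  22.1788  22.1788  20.2000
GT  42.9294  19.2106  34.5575  34.5575  19.2106
GP  41.5976  11.6864  32.3805  39.7200   6.2197
F   51.4800  12.2800  14.2588  32.4810  12.2800
```

Rows are the focal player. Two GP partners earn 39.72 each — almost the full
cooperative value 2 × 20 = 40, because they forgive each other's accidents —
while a faker facing GP earns only 32.48: each defection costs it 0.4 and
its apologies are eventually disbelieved. Since E(GP,GP) = 39.72 exceeds
E(F,GP) = 32.48 (and the analogous margins against C, D, GT hold),
guilt-proneness is evolutionarily stable here.

How likely is it to evolve? From 2,000 random initial mixes of {C, D, GP, F}:

```
$ guiltgame basin --samples 2000 --seed 7
  D: 0.6895  (95% CI 0.6689-0.7094)
 GP: 0.3105  (95% CI 0.2906-0.3311)
```

About 31% of random starting populations evolve to all-guilt-prone; the rest
end at all-defect. Sweeping the shared cost c = d shows this basin is
largest at intermediate cost: cheap apologies let fakers thrive, expensive
ones bleed the guilt-prone themselves.

The `experiment` subcommand packages these sweeps (`ess-cost`,
`ess-continuation`, `basin-cost`, `basin-faker-cost`) with CSV output, JSON
metadata sidecars and matching plots, e.g.

```sh
guiltgame experiment basin-cost --samples 10000 --seed 1 --out basin_cost.csv
guiltgame plot basin_cost.csv --preset basin-cost --out basin_cost.png
```

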