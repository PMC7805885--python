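"""Payoff-engine tests: encounter chains, the linear solve, the MC oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from guiltgame import (
    ModelParams,
    ParameterError,
    Strategy,
    build_pair_process,
    build_payoff_matrix,
    expected_apologies,
    expected_pair_payoffs,
    expected_rounds,
    mc_pair_payoffs,
)
from guiltgame.model import ALL_STRATEGIES

STRATEGY_PAIRS = list(itertools.combinations_with_replacement(ALL_STRATEGIES, 2))

params_st = st.builds(
    lambda n, a, p, c, extra: ModelParams(n=n, a=a, p=p, c=c, d=c + extra),
    n=st.sampled_from([0.0, 0.5, 0.9, 0.95, 0.99]),
    a=st.sampled_from([0.0, 0.01, 0.05, 0.2]),
    p=st.sampled_from([0.1, 0.5, 0.95, 1.0]),
    c=st.sampled_from([0.0, 0.2, 1.0]),
    extra=st.sampled_from([0.0, 0.3]),
)


class TestExpectedRounds:
    @pytest.mark.parametrize("n, expected", [(0.95, 20.0), (0.0, 1.0), (0.5, 2.0)])
    def test_geometric_mean_length(self, n, expected):
        assert expected_rounds(n) == pytest.approx(expected)

    @pytest.mark.parametrize("n", [1.0, 1.5, -0.2])
    def test_invalid_continuation_rejected(self, n):
        with pytest.raises(ParameterError):
            expected_rounds(n)


class TestPairProcess:
    @given(params_st, st.sampled_from(STRATEGY_PAIRS))
    def test_transition_rows_sum_to_one(self, params, pair):
        proc = build_pair_process(*pair, params)
        rows = proc.transition.sum(axis=1)
        assert np.allclose(rows, 1.0, atol=1e-12)

    @given(params_st, st.sampled_from(STRATEGY_PAIRS))
    def test_rewards_bounded_and_state_count_small(self, params, pair):
        proc = build_pair_process(*pair, params)
        assert len(proc.states) <= 4
        lo = -max(params.c, params.d)
        assert np.all(proc.rewards >= lo - 1e-12)
        assert np.all(proc.rewards <= 3.0 + 1e-12)

    def test_mutual_defectors_single_state_reward(self):
        proc = build_pair_process(Strategy.D, Strategy.D, ModelParams(a=0.0))
        assert len(proc.states) == 1
        assert proc.rewards[0, 0] == pytest.approx(1.0)
        a = 0.05
        proc = build_pair_process(Strategy.D, Strategy.D, ModelParams(a=a))
        expected = (1 - a) ** 2 * 1 + a * (1 - a) * 3 + a * (1 - a) * 0 + a**2 * 2
        assert proc.rewards[0, 0] == pytest.approx(expected)

    def test_guilt_prone_pair_closed_form_reward(self):
        # hand enumeration: stage mix minus the apology cost paid at rate a
        a, c = 0.01, 0.2
        proc = build_pair_process(
            Strategy.GP, Strategy.GP, ModelParams(a=a, c=c, d=c)
        )
        closed_form = 2 * (1 - a) ** 2 + 3 * a * (1 - a) + 0 * a * (1 - a) + a**2 - a * c
        assert closed_form == pytest.approx(1.988)
        assert proc.rewards[proc.initial, 0] == pytest.approx(closed_form)
        # mutual forgiveness keeps the cooperative state absorbing
        assert proc.transition[proc.initial, proc.initial] == pytest.approx(1.0)

    def test_guilt_prone_vs_faker_punishment_hazard(self):
        # GP turns punitive exactly when F's realized defection goes unbelieved
        a, p = 0.01, 0.95
        proc = build_pair_process(
            Strategy.GP, Strategy.F, ModelParams(a=a, p=p)
        )
        start = proc.initial
        hazard = sum(
            proc.transition[start, k]
            for k, (m1, _) in enumerate(proc.states)
            if m1.value == "punishing"
        )
        assert hazard == pytest.approx((1 - a) * (1 - p))


class TestExpectedPayoffs:
    def test_pure_cooperators_noise_free(self):
        proc = build_pair_process(Strategy.C, Strategy.C, ModelParams(a=0.0))
        assert expected_pair_payoffs(proc, 0.95) == pytest.approx((40.0, 40.0))

    def test_guilt_prone_pair_total(self):
        params = ModelParams(a=0.01, c=0.2, d=0.2, n=0.95)
        proc = build_pair_process(Strategy.GP, Strategy.GP, params)
        v1, v2 = expected_pair_payoffs(proc, params.n)
        assert v1 == pytest.approx(39.76)
        assert v2 == pytest.approx(39.76)

    @given(params_st, st.sampled_from(STRATEGY_PAIRS))
    def test_single_round_limit(self, params, pair):
        proc = build_pair_process(*pair, params)
        v1, v2 = expected_pair_payoffs(proc, 0.0)
        assert v1 == pytest.approx(proc.rewards[proc.initial, 0])
        assert v2 == pytest.approx(proc.rewards[proc.initial, 1])

    def test_error_free_conditional_cooperators_all_equal(self):
        params = ModelParams(a=0.0, n=0.9, c=0.7, d=0.7)
        vals = {}
        for s in (Strategy.C, Strategy.GT, Strategy.GP):
            proc = build_pair_process(s, s, params)
            vals[s] = expected_pair_payoffs(proc, params.n)[0]
        assert vals[Strategy.C] == pytest.approx(2 / (1 - params.n))
        assert vals[Strategy.GT] == pytest.approx(vals[Strategy.C])
        assert vals[Strategy.GP] == pytest.approx(vals[Strategy.C])

    def test_self_play_monotone_in_cost_and_continuation(self):
        def gp_self(c, n):
            params = ModelParams(a=0.01, c=c, d=c, n=n)
            proc = build_pair_process(Strategy.GP, Strategy.GP, params)
            return expected_pair_payoffs(proc, n)[0]

        costs = [0.0, 0.2, 0.5, 1.0]
        values = [gp_self(c, 0.95) for c in costs]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))
        ns = [0.5, 0.9, 0.95, 0.99]
        values = [gp_self(0.2, n) for n in ns]
        assert all(b > a for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("pair", [(Strategy.GP, Strategy.GP),
                                      (Strategy.GP, Strategy.D),
                                      (Strategy.GP, Strategy.F)])
    def test_cost_sensitivity_equals_expected_apology_count(self, pair):
        # d(value)/dc = -(expected apologies per encounter) by linearity
        n, h = 0.95, 1e-6
        base = ModelParams(a=0.01, c=0.4, d=0.4, n=n)
        # bumping d as well keeps d >= c; player 1's value depends only on c
        bumped = base.replace(c=0.4 + h, d=0.4 + h)
        v0 = expected_pair_payoffs(build_pair_process(*pair, base), n)[0]
        v1 = expected_pair_payoffs(build_pair_process(*pair, bumped), n)[0]
        apologies = expected_apologies(build_pair_process(*pair, base), n)[0]
        assert (v1 - v0) / h == pytest.approx(-apologies, rel=1e-4)

    def test_row_column_symmetry_across_orderings(self, default_params):
        for s1, s2 in STRATEGY_PAIRS:
            fwd = expected_pair_payoffs(
                build_pair_process(s1, s2, default_params), default_params.n
            )
            rev = expected_pair_payoffs(
                build_pair_process(s2, s1, default_params), default_params.n
            )
            assert fwd[0] == pytest.approx(rev[1], abs=1e-9)
            assert fwd[1] == pytest.approx(rev[0], abs=1e-9)


class TestMonteCarloOracle:
    def test_reproducible_from_seed(self, default_params):
        one = mc_pair_payoffs(Strategy.GP, Strategy.F, default_params, reps=500, seed=7)
        two = mc_pair_payoffs(Strategy.GP, Strategy.F, default_params, reps=500, seed=7)
        assert one == two

    def test_mutual_defection_closed_form(self):
        params = ModelParams(a=0.0, n=0.5, c=0.0, d=0.0)
        (m1, s1), _ = mc_pair_payoffs(Strategy.D, Strategy.D, params, reps=100_000, seed=3)
        # P = 1 per round, expected 2 rounds
        assert abs(m1 - 2.0) < 3 * s1

    def test_guilt_prone_pair_matches_analytic(self):
        params = ModelParams(a=0.01, c=0.2, d=0.2, n=0.95)
        (m1, s1), (m2, s2) = mc_pair_payoffs(
            Strategy.GP, Strategy.GP, params, reps=100_000, seed=11
        )
        assert abs(m1 - 39.76) < 3 * s1
        assert abs(m2 - 39.76) < 3 * s2

    @pytest.mark.parametrize(
        "params",
        [
            ModelParams(n=0.5, a=0.0, p=0.5, c=0.0, d=0.0),
            ModelParams(n=0.9, a=0.05, p=0.1, c=0.2, d=0.2),
            ModelParams(n=0.95, a=0.01, p=0.95, c=0.4, d=0.4),
            ModelParams(n=0.95, a=0.01, p=0.95, c=0.0, d=0.6),
            ModelParams(n=0.99, a=0.01, p=0.5, c=1.0, d=1.0),
        ],
        ids=["noise-free", "high-noise", "headline", "asymmetric", "long"],
    )
    def test_analytic_within_monte_carlo_error(self, params):
        rng = np.random.default_rng(2024)
        for s1, s2 in STRATEGY_PAIRS:
            analytic = expected_pair_payoffs(build_pair_process(s1, s2, params), params.n)
            (m1, se1), (m2, se2) = mc_pair_payoffs(s1, s2, params, reps=20_000, seed=rng)
            for got, (mean, se) in zip(analytic, [(m1, se1), (m2, se2)]):
                if se > 0:
                    assert abs(mean - got) < 4 * se, (s1, s2, params)
                else:  # degenerate: deterministic totals
                    assert mean == pytest.approx(got, abs=1e-9)


class TestPayoffMatrix:
    def test_one_shot_noise_free_matrix_is_the_stage_game(self):
        matrix = build_payoff_matrix(
            (Strategy.C, Strategy.D), ModelParams(n=0.0, a=0.0)
        )
        assert matrix.value(Strategy.C, Strategy.C) == pytest.approx(2.0)
        assert matrix.value(Strategy.C, Strategy.D) == pytest.approx(0.0)
        assert matrix.value(Strategy.D, Strategy.C) == pytest.approx(3.0)
        assert matrix.value(Strategy.D, Strategy.D) == pytest.approx(1.0)

    def test_duplicate_strategies_rejected(self, default_params):
        with pytest.raises(ValueError):
            build_payoff_matrix((Strategy.C, Strategy.C), default_params)

    def test_grim_variants_coincide_without_noise(self):
        matrix = build_payoff_matrix(
            (Strategy.GT, Strategy.GP), ModelParams(a=0.0, c=0.9, d=0.9)
        )
        assert matrix.value(Strategy.GT, Strategy.GT) == pytest.approx(
            matrix.value(Strategy.GP, Strategy.GP)
        )

    def test_round_trip_exports(self, default_params, tmp_path):
        import json

        import pandas as pd

        matrix = build_payoff_matrix((Strategy.C, Strategy.D, Strategy.GP), default_params)
        csv_path = tmp_path / "matrix.csv"
        matrix.to_csv(csv_path)
        frame = pd.read_csv(csv_path, index_col=0)
        assert np.allclose(frame.values, matrix.values)
        payload = json.loads(matrix.to_json())
        assert payload["params"]["n"] == default_params.n
        assert np.allclose(payload["values"], matrix.values)
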