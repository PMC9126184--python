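import math

import numpy as np
import pytest
from scipy import stats

from prunechain.core import Environment, Solution, stack_environments
from prunechain.planner import (
    GameStack,
    PruningParams,
    expected_reward,
    gamma_for,
    policy,
    q_values,
    sample_actions_batch,
    sample_solution,
    solution_loglik,
)
from prunechain.envgen import optimal_path

import oracles
from conftest import make_uniform_reward_env


class TestGammaFor:
    @pytest.mark.parametrize(
        "reward, expected",
        [(-100, 0.45), (-20, 0.2), (20, 0.2), (140, 0.2)],
    )
    def test_large_cost_selects_specific_rate(self, reward, expected):
        params = PruningParams(gamma_g=0.2, gamma_s=0.45, beta=0.03)
        assert gamma_for(reward, params) == expected

    def test_reward_outside_payoff_set_rejected(self):
        with pytest.raises(ValueError, match="payoff"):
            gamma_for(50, PruningParams(0.2, 0.45, 0.03))

    def test_equal_rates_make_pruning_reward_independent(self):
        params = PruningParams(gamma_g=0.3, gamma_s=0.3, beta=0.01)
        assert len({gamma_for(r, params) for r in (-100, -20, 20, 140)}) == 1


class TestQValues:
    def test_no_pruning_recovers_optimal_total(self, random_envs):
        params = PruningParams(0.0, 0.0, 0.03)
        for env in random_envs[:20]:
            qt = q_values(env, params)
            v8 = max(qt.value(8, env.start, 0), qt.value(8, env.start, 1))
            assert v8 == pytest.approx(optimal_path(env).total_reward, abs=1e-9)

    def test_full_pruning_collapses_to_immediate_reward(self, toy_env):
        qt = q_values(toy_env, PruningParams(1.0, 1.0, 0.03))
        for d in (1, 4, 8):
            np.testing.assert_allclose(qt.q[d - 1], toy_env.rewards)

    def test_recursion_matches_brute_force_discounted_maximum(self, random_envs):
        # oracle equivalence over 100 random (environment, params) pairs
        rng = np.random.default_rng(5)
        for env in random_envs:
            params = PruningParams(
                float(rng.uniform(0, 1)), float(rng.uniform(0, 1)), 0.03
            )
            qt = q_values(env, params)
            v8 = max(qt.value(8, env.start, 0), qt.value(8, env.start, 1))
            assert v8 == pytest.approx(
                oracles.brute_discounted_max(env, params), abs=1e-9
            )

    def test_table_export_round_trips_values(self, toy_env):
        params = PruningParams(0.2, 0.45, 0.012)
        qt = q_values(toy_env, params)
        frame = qt.to_frame()
        assert list(frame.columns) == ["depth", "state", "action", "value"]
        assert len(frame) == 8 * 6 * 2
        row = frame[(frame.depth == 5) & (frame.state == 3) & (frame.action == 1)]
        assert float(row.value.iloc[0]) == qt.value(5, 3, 1)
        pol = policy(toy_env, params)
        pframe = pol.to_frame()
        assert pframe.groupby(["depth", "state"]).probability.sum().round(12).eq(1).all()

    def test_terminal_depth_equals_immediate_reward(self, random_envs):
        params = PruningParams(0.2, 0.45, 0.012)
        for env in random_envs[:10]:
            np.testing.assert_array_equal(q_values(env, params).q[0], env.rewards)


class TestPolicy:
    def test_zero_temperature_is_uniform(self, toy_env):
        pol = policy(toy_env, PruningParams(0.3, 0.6, 0.0))
        np.testing.assert_allclose(pol.probs, 0.5)

    def test_logistic_evaluation_of_known_value_gap(self):
        # Q difference of 40 at beta = 0.03 gives 1 / (1 + e^{-1.2})
        env = make_uniform_reward_env(20)
        # depth-1 policy acts on immediate rewards only; craft a gap of 40
        env2 = Environment(env.network, start=0)
        pol = policy(env2, PruningParams(0.0, 0.0, 0.03))
        qt = q_values(env2, PruningParams(0.0, 0.0, 0.03))
        d, s = 3, 2
        gap = qt.value(d, s, 0) - qt.value(d, s, 1)
        expected = 1.0 / (1.0 + math.exp(-0.03 * gap))
        assert pol.prob(d, s, 0) == pytest.approx(expected, abs=1e-12)
        assert 1.0 / (1.0 + math.exp(-1.2)) == pytest.approx(
            0.7685247834990175, abs=1e-12
        )

    def test_rows_sum_to_one(self, random_envs):
        rng = np.random.default_rng(3)
        for env in random_envs[:20]:
            params = PruningParams(
                float(rng.uniform(0, 1)), float(rng.uniform(0, 1)),
                float(rng.uniform(0, 0.1)),
            )
            pol = policy(env, params)
            np.testing.assert_allclose(pol.probs.sum(axis=-1), 1.0, atol=1e-12)

    def test_greedy_limit(self, random_envs):
        env = random_envs[0]
        pol = policy(env, PruningParams(0.2, 0.45, 1e6))
        qt = q_values(env, PruningParams(0.2, 0.45, 1e6))
        for d in range(1, 9):
            for s in range(6):
                if abs(qt.value(d, s, 0) - qt.value(d, s, 1)) > 1e-6:
                    best = int(np.argmax([qt.value(d, s, 0), qt.value(d, s, 1)]))
                    assert pol.prob(d, s, best) == pytest.approx(1.0, abs=1e-9)

    def test_entropy_nonincreasing_in_beta(self, toy_env):
        def entropy(p):
            p = np.clip(p, 1e-300, 1.0)
            return -(p * np.log(p)).sum(axis=-1)

        previous = None
        for beta in (0.0, 0.005, 0.01, 0.02, 0.05, 0.1):
            pol = policy(toy_env, PruningParams(0.2, 0.45, beta))
            h = entropy(pol.probs)
            if previous is not None:
                assert np.all(h <= previous + 1e-12)
            previous = h


class TestExpectedReward:
    def test_uniform_policy_averages_all_paths(self, random_envs):
        for env in random_envs[:10]:
            got = expected_reward(env, PruningParams(0.3, 0.5, 0.0))
            assert got == pytest.approx(oracles.uniform_expected_total(env), abs=1e-9)

    def test_greedy_no_pruning_approaches_optimum(self, random_envs):
        env = random_envs[1]
        got = expected_reward(env, PruningParams(0.0, 0.0, 1e3))
        assert got == pytest.approx(optimal_path(env).total_reward, abs=1e-6)

    def test_deterministic_policy_equals_induced_path_reward(self, toy_env):
        params = PruningParams(0.2, 0.45, 1e5)
        pol = policy(toy_env, params)
        state, total = toy_env.start, 0
        for step in range(8):
            a = int(pol.probs[8 - 1 - step, state].argmax())
            total += int(toy_env.rewards[state, a])
            state = int(toy_env.targets[state, a])
        assert expected_reward(toy_env, params) == pytest.approx(total, abs=1e-6)

    def test_matches_monte_carlo_sampling(self, random_envs):
        params = PruningParams(0.2, 0.45, 0.012)
        envs = random_envs[:3]
        batch = stack_environments(envs)
        rng = np.random.default_rng(11)
        n = 100_000
        for i, env in enumerate(envs):
            _, _, rewards = sample_actions_batch(
                batch.targets, batch.rewards, batch.start, params,
                np.full(n, i), rng,
            )
            totals = rewards.sum(axis=1)
            se = totals.std(ddof=1) / math.sqrt(n)
            assert expected_reward(env, params) == pytest.approx(
                totals.mean(), abs=3 * se
            )


class TestLikelihood:
    def test_uniform_policy_loglik_is_count_times_log_half(self, random_envs):
        rng = np.random.default_rng(2)
        games = [
            (env, Solution.from_actions(env, rng.integers(0, 2, 8)))
            for env in random_envs[:6]
        ]
        got = solution_loglik(games, PruningParams(0.3, 0.6, 0.0))
        assert got == pytest.approx(-6 * 8 * math.log(2), abs=1e-9)

    def test_toy_game_matches_stepwise_softmax(self, toy_env):
        params = PruningParams(0.2, 0.45, 0.012)
        sol = Solution.from_actions(toy_env, [0, 1, 0, 0, 1, 0, 0, 0])
        # independent route: per-step softmax of brute-force subtree values
        expected = 0.0
        for step in range(8):
            s = sol.states[step]
            depth = 8 - step
            vals = []
            for a in (0, 1):
                sub = Environment(toy_env.network, start=s)
                # discounted subtree value of taking a then acting optimally
                r = int(toy_env.rewards[s, a])
                if depth == 1:
                    vals.append(float(r))
                    continue
                nxt = Environment(toy_env.network, start=int(toy_env.targets[s, a]))
                cont = _brute_value(nxt, params, depth - 1)
                vals.append(r + (1 - gamma_for(r, params)) * cont)
            z = np.array(vals) * params.beta
            logp = z - np.log(np.exp(z - z.max()).sum()) - z.max()
            expected += logp[sol.actions[step]]
        got = solution_loglik([(toy_env, sol)], params)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_order_invariance(self, random_envs):
        rng = np.random.default_rng(4)
        games = [
            (env, Solution.from_actions(env, rng.integers(0, 2, 8)))
            for env in random_envs[:8]
        ]
        params = PruningParams(0.25, 0.5, 0.02)
        assert solution_loglik(games, params) == pytest.approx(
            solution_loglik(games[::-1], params), abs=1e-12
        )

    def test_foreign_solution_rejected(self, toy_env, myopic_env):
        sol = Solution.from_actions(myopic_env, [1] * 8)
        with pytest.raises(ValueError):
            solution_loglik([(toy_env, sol)], PruningParams(0.2, 0.45, 0.012))

    def test_bootstrap_subset_indexes_whole_games(self, random_envs):
        rng = np.random.default_rng(6)
        games = [
            (env, Solution.from_actions(env, rng.integers(0, 2, 8)))
            for env in random_envs[:5]
        ]
        stack = GameStack(games)
        sub = stack.subset(np.array([0, 0, 3]))
        params = PruningParams(0.2, 0.45, 0.012)
        direct = GameStack([games[0], games[0], games[3]])
        assert sub.loglik(params) == pytest.approx(direct.loglik(params), abs=1e-12)


def _brute_value(env: Environment, params: PruningParams, depth: int) -> float:
    """Max discounted value over all depth-step action sequences (recursive)."""
    best = -np.inf
    for a in (0, 1):
        r = int(env.rewards[env.start, a])
        if depth == 1:
            val = float(r)
        else:
            nxt = Environment(env.network, start=int(env.targets[env.start, a]))
            val = r + (1 - gamma_for(r, params)) * _brute_value(nxt, params, depth - 1)
        best = max(best, val)
    return best


class TestSampling:
    def test_samples_are_valid_solutions(self, random_envs):
        rng = np.random.default_rng(8)
        for env in random_envs[:10]:
            sol = sample_solution(env, PruningParams(0.2, 0.45, 0.012), rng)
            assert len(sol.moves) == 8
            assert sol.states[0] == env.start

    def test_greedy_sampling_returns_optimal_path(self, random_envs):
        env = random_envs[2]
        opt = optimal_path(env).total_reward
        rng = np.random.default_rng(9)
        for _ in range(20):
            sol = sample_solution(env, PruningParams(0.0, 0.0, 1e5), rng)
            assert sol.total_reward == opt

    def test_empirical_frequencies_match_policy(self, random_envs):
        # per-(depth, state) move frequencies at n = 10,000 agree with the
        # policy table (no Bonferroni-corrected binomial rejection at 0.001)
        env = random_envs[3]
        params = PruningParams(0.2, 0.45, 0.03)
        pol = policy(env, params)
        batch = stack_environments([env])
        n = 10_000
        states, actions, _ = sample_actions_batch(
            batch.targets, batch.rewards, batch.start, params,
            np.zeros(n, dtype=int), np.random.default_rng(10),
        )
        n_tests = 0
        pvals = []
        for step in range(8):
            depth_idx = 8 - 1 - step
            for s in np.unique(states[:, step]):
                mask = states[:, step] == s
                if mask.sum() < 50:
                    continue
                k = int(actions[mask, step].sum())
                p = float(pol.probs[depth_idx, s, 1])
                pvals.append(stats.binomtest(k, int(mask.sum()), p).pvalue)
                n_tests += 1
        assert n_tests > 10
        assert min(pvals) > 0.001 / n_tests
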