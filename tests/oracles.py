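"""Independent brute-force oracles used by the tests.

Everything here enumerates the 2^8 = 256 action sequences of an environment
directly and never calls the recursive planner, so it can serve as an
independent check of the dynamic-programming implementations.
"""

from __future__ import annotations

import itertools

import numpy as np

from prunechain.core import HORIZON, Environment, Solution
from prunechain.planner import PruningParams, gamma_for


def all_solutions(env: Environment) -> list[Solution]:
    """All 256 eight-move walks from the start node."""
    return [
        Solution.from_actions(env, acts)
        for acts in itertools.product((0, 1), repeat=HORIZON)
    ]


def brute_optimal_total(env: Environment) -> int:
    """Maximum total reward by exhaustive path enumeration."""
    return max(s.total_reward for s in all_solutions(env))


def brute_discounted_max(env: Environment, params: PruningParams) -> float:
    """Maximum pruning-discounted path value by exhaustive enumeration.

    A reward k steps into a path is weighted by the product of (1 - gamma)
    factors of the k - 1 moves before it, each factor chosen by that move's
    own payoff.
    """
    best = -np.inf
    for acts in itertools.product((0, 1), repeat=HORIZON):
        state = env.start
        total = 0.0
        discount = 1.0
        for a in acts:
            r = int(env.rewards[state, a])
            total += discount * r
            discount *= 1.0 - gamma_for(r, params)
            state = int(env.targets[state, a])
        best = max(best, total)
    return best


def path_probability(env: Environment, sol: Solution, probs: np.ndarray) -> float:
    """Probability of a solution under a depth-indexed policy table."""
    p = 1.0
    for step in range(HORIZON):
        depth_idx = HORIZON - 1 - step
        p *= probs[depth_idx, sol.states[step], sol.actions[step]]
    return p


def uniform_expected_total(env: Environment) -> float:
    """Mean total reward over the 256 equiprobable paths."""
    return float(np.mean([s.total_reward for s in all_solutions(env)]))
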