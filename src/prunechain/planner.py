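"""Selective (aversive) pruning decision model.

The model plans over a finite horizon on a reward network by a Bellman-style
backward recursion in which the continuation value after a move is discounted
by a pruning factor that depends on the move's immediate payoff:

    Q_d(a, s) = R(a, s) + (1 - gamma(a, s)) * max_a' Q_{d-1}(a', T(a, s))

with ``Q_1(a, s) = R(a, s)``.  The pruning rate ``gamma(a, s)`` equals a
*specific* rate ``gamma_s`` when the move carries a large cost (payoff -100)
and a *general* rate ``gamma_g`` otherwise.  Equivalently, a reward ``k``
steps ahead along a path is discounted by the product of ``(1 - gamma)``
factors of the ``k - 1`` moves preceding it.  Choices follow a softmax
(logit) policy over the two available actions with inverse temperature
``beta``.

Humans show *aversive pruning*: ``gamma_s > gamma_g``, i.e. branches behind a
large cost are discounted more heavily.  The study's algorithmic player
reverses this bias (``gamma_s < gamma_g``).

Depth convention: moves are indexed 1..8 and the *remaining depth* at move
``i`` is ``d = 9 - i``; the final move uses ``Q_1`` = immediate reward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    HORIZON,
    LARGE_COST,
    N_ACTIONS,
    N_NODES,
    REWARD_VALUES,
    Environment,
    Solution,
    validate_solution,
)

__all__ = [
    "PruningParams",
    "QTable",
    "PolicyTable",
    "gamma_for",
    "q_values",
    "q_values_batch",
    "policy",
    "policy_batch",
    "log_policy_batch",
    "expected_reward",
    "expected_reward_batch",
    "solution_loglik",
    "GameStack",
    "sample_solution",
    "sample_actions_batch",
]


@dataclass(frozen=True)
class PruningParams:
    """Parameters of the aversive-pruning model.

    Attributes
    ----------
    gamma_g
        General pruning rate in [0, 1], applied after moves that do not
        carry a large cost.
    gamma_s
        Specific pruning rate in [0, 1], applied after large-cost moves.
    beta
        Softmax inverse temperature (>= 0); 0 gives uniform random choice.
    large_cost
        Payoff value that triggers the specific rate (default -100).
    """

    gamma_g: float
    gamma_s: float
    beta: float
    large_cost: int = LARGE_COST

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_g <= 1.0:
            raise ValueError(f"gamma_g={self.gamma_g} outside [0, 1]")
        if not 0.0 <= self.gamma_s <= 1.0:
            raise ValueError(f"gamma_s={self.gamma_s} outside [0, 1]")
        if self.beta < 0.0:
            raise ValueError(f"beta={self.beta} must be non-negative")


def gamma_for(reward: int, params: PruningParams) -> float:
    """Pruning rate applied to the continuation after a move with ``reward``."""
    if reward not in REWARD_VALUES:
        raise ValueError(f"reward {reward} not in the payoff set {REWARD_VALUES}")
    return params.gamma_s if reward == params.large_cost else params.gamma_g


@dataclass(frozen=True)
class QTable:
    """State-action values indexed by remaining depth.

    ``q`` has shape ``(horizon, 6, 2)``; ``q[d-1, s, a]`` is the value of
    action ``a`` in state ``s`` with ``d`` moves remaining.
    """

    q: np.ndarray

    @property
    def horizon(self) -> int:
        return self.q.shape[0]

    def value(self, depth: int, state: int, action: int) -> float:
        return float(self.q[depth - 1, state, action])

    def to_frame(self):
        """Long-format table (depth, state, action, value) for debugging."""
        return _table_to_frame(self.q, "value")


@dataclass(frozen=True)
class PolicyTable:
    """Softmax choice probabilities indexed like :class:`QTable`."""

    probs: np.ndarray

    @property
    def horizon(self) -> int:
        return self.probs.shape[0]

    def prob(self, depth: int, state: int, action: int) -> float:
        return float(self.probs[depth - 1, state, action])

    def to_frame(self):
        """Long-format table (depth, state, action, probability)."""
        return _table_to_frame(self.probs, "probability")


def _table_to_frame(arr: np.ndarray, value_name: str):
    import pandas as pd

    h = arr.shape[0]
    depth, state, action = np.meshgrid(
        np.arange(1, h + 1), np.arange(N_NODES), np.arange(N_ACTIONS), indexing="ij"
    )
    return pd.DataFrame(
        {
            "depth": depth.ravel(),
            "state": state.ravel(),
            "action": action.ravel(),
            value_name: arr.ravel(),
        }
    )


def _gamma_grid(rewards: np.ndarray, params: PruningParams) -> np.ndarray:
    return np.where(rewards == params.large_cost, params.gamma_s, params.gamma_g)


def q_values_batch(
    targets: np.ndarray,
    rewards: np.ndarray,
    params: PruningParams,
    horizon: int = HORIZON,
) -> np.ndarray:
    """Backward recursion over a batch of networks.

    ``targets``/``rewards`` have shape ``(E, 6, 2)``; returns
    ``(horizon, E, 6, 2)``.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    e = targets.shape[0]
    gam = _gamma_grid(rewards, params)
    q = np.empty((horizon, e, N_NODES, N_ACTIONS), dtype=np.float64)
    q[0] = rewards
    ei = np.arange(e)[:, None, None]
    for d in range(1, horizon):
        v_next = q[d - 1].max(axis=-1)  # (E, 6)
        q[d] = rewards + (1.0 - gam) * v_next[ei, targets]
    return q


def q_values(env: Environment, params: PruningParams, horizon: int = HORIZON) -> QTable:
    """Pruned state-action values for one environment."""
    q = q_values_batch(env.targets[None], env.rewards[None], params, horizon)
    return QTable(q[:, 0])


def _log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def policy_batch(q: np.ndarray, beta: float) -> np.ndarray:
    """Softmax policy over the last (action) axis, numerically stabilized."""
    return np.exp(_log_softmax(beta * q))


def log_policy_batch(q: np.ndarray, beta: float) -> np.ndarray:
    return _log_softmax(beta * q)


def policy(env: Environment, params: PruningParams, horizon: int = HORIZON) -> PolicyTable:
    """Depth-indexed softmax policy for one environment."""
    q = q_values(env, params, horizon)
    return PolicyTable(policy_batch(q.q, params.beta))


def expected_reward_batch(
    targets: np.ndarray,
    rewards: np.ndarray,
    start: np.ndarray,
    params: PruningParams,
    horizon: int = HORIZON,
) -> np.ndarray:
    """Exact expected total (undiscounted) reward of an episode per environment.

    Propagates the state distribution forward through the depth-indexed
    policy; no sampling is involved.
    """
    e = targets.shape[0]
    q = q_values_batch(targets, rewards, params, horizon)
    pi = policy_batch(q, params.beta)
    dist = np.zeros((e, N_NODES), dtype=np.float64)
    dist[np.arange(e), start] = 1.0
    total = np.zeros(e, dtype=np.float64)
    ei = np.arange(e)[:, None]
    for step in range(horizon):
        depth_idx = horizon - 1 - step  # remaining depth d = horizon - step
        flow = dist[:, :, None] * pi[depth_idx]  # (E, 6, 2)
        total += (flow * rewards).sum(axis=(1, 2))
        nxt = np.zeros_like(dist)
        for a in range(N_ACTIONS):
            np.add.at(nxt, (ei, targets[:, :, a]), flow[:, :, a])
        dist = nxt
    return total


def expected_reward(env: Environment, params: PruningParams, horizon: int = HORIZON) -> float:
    """Exact expected episode reward under the pruning policy."""
    return float(
        expected_reward_batch(
            env.targets[None],
            env.rewards[None],
            np.array([env.start]),
            params,
            horizon,
        )[0]
    )


class GameStack:
    """Pre-indexed observed moves for fast repeated likelihood evaluation.

    Groups the games by environment, stacks the unique environments into
    arrays and flattens every observed move into ``(env, depth, state,
    action)`` index vectors, so that the log-likelihood at any parameter
    vector is a couple of vectorized array operations.
    """

    def __init__(self, games: Sequence[tuple[Environment, Solution]], horizon: int = HORIZON):
        if not games:
            raise ValueError("no games supplied")
        env_index: dict[int, int] = {}
        uniq_envs: list[Environment] = []
        ei, di, si, ai = [], [], [], []
        for env, sol in games:
            validate_solution(env, sol)
            key = hash((env.network, env.start))
            idx = env_index.get(key)
            if idx is None:
                idx = len(uniq_envs)
                env_index[key] = idx
                uniq_envs.append(env)
            for step in range(horizon):
                ei.append(idx)
                di.append(horizon - 1 - step)
                si.append(sol.states[step])
                ai.append(sol.actions[step])
        self.horizon = horizon
        self.n_games = len(games)
        self.targets = np.stack([e.targets for e in uniq_envs])
        self.rewards = np.stack([e.rewards for e in uniq_envs])
        self._ei = np.array(ei)
        self._di = np.array(di)
        self._si = np.array(si)
        self._ai = np.array(ai)

    @property
    def n_moves(self) -> int:
        return self._ei.size

    def loglik(self, params: PruningParams) -> float:
        q = q_values_batch(self.targets, self.rewards, params, self.horizon)
        logp = log_policy_batch(q, params.beta)
        return float(logp[self._di, self._ei, self._si, self._ai].sum())

    def subset(self, game_indices: np.ndarray) -> "GameStack":
        """Resampled view over whole games (bootstrap unit = one game)."""
        new = object.__new__(GameStack)
        new.horizon = self.horizon
        new.n_games = len(game_indices)
        new.targets = self.targets
        new.rewards = self.rewards
        move_idx = (
            np.asarray(game_indices)[:, None] * self.horizon
            + np.arange(self.horizon)[None, :]
        ).ravel()
        new._ei = self._ei[move_idx]
        new._di = self._di[move_idx]
        new._si = self._si[move_idx]
        new._ai = self._ai[move_idx]
        return new


def solution_loglik(
    games: Sequence[tuple[Environment, Solution]], params: PruningParams
) -> float:
    """Log-likelihood of observed solutions under the pruning policy.

    Sums ``log pi(move | state, remaining depth)`` over every move of every
    game.  Raises ``ValueError`` if any move is not an edge from the current
    state.
    """
    return GameStack(games).loglik(params)


def sample_solution(
    env: Environment, params: PruningParams, rng: np.random.Generator | int | None = None
) -> Solution:
    """Draw one eight-move solution from the softmax pruning policy."""
    rng = np.random.default_rng(rng)
    pol = policy(env, params)
    state = env.start
    actions = []
    for step in range(HORIZON):
        depth = HORIZON - step
        p1 = pol.prob(depth, state, 1)
        a = int(rng.random() < p1)
        actions.append(a)
        state = int(env.targets[state, a])
    return Solution.from_actions(env, actions)


def sample_actions_batch(
    targets: np.ndarray,
    rewards: np.ndarray,
    start: np.ndarray,
    params: PruningParams,
    env_idx: np.ndarray,
    rng: np.random.Generator,
    horizon: int = HORIZON,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized policy sampling: one solution per entry of ``env_idx``.

    Returns ``(states, actions, move_rewards)`` with shapes
    ``(N, horizon + 1)``, ``(N, horizon)``, ``(N, horizon)``.
    """
    q = q_values_batch(targets, rewards, params, horizon)
    pi = policy_batch(q, params.beta)
    n = env_idx.size
    states = np.empty((n, horizon + 1), dtype=np.int64)
    actions = np.empty((n, horizon), dtype=np.int64)
    move_rewards = np.empty((n, horizon), dtype=np.int64)
    states[:, 0] = start[env_idx]
    u = rng.random((n, horizon))
    for step in range(horizon):
        depth_idx = horizon - 1 - step
        s = states[:, step]
        p1 = pi[depth_idx, env_idx, s, 1]
        a = (u[:, step] < p1).astype(np.int64)
        actions[:, step] = a
        move_rewards[:, step] = rewards[env_idx, s, a]
        states[:, step + 1] = targets[env_idx, s, a]
    return states, actions, move_rewards
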