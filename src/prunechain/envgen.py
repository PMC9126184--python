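"""Generation, filtering and classification of planning environments.

The pipeline mirrors the study design it emulates:

1. rejection-sample strongly connected 6-node networks with out-degree 2 and
   uniform edge payoffs from (-100, -20, 20, 140);
2. form one candidate environment per (network, start node) pair — six per
   network;
3. drop environments whose optimal eight-move reward lies in the upper or
   lower quartile of the pool (reduces reward-scale variation);
4. drop environments whose optimal path is trivial: it must visit at least
   four distinct nodes and contain at least four *non-myopic* steps (steps
   at which the optimal move's immediate payoff is no larger than the
   alternative's);
5. score each survivor by its *aversive-pruning sensitivity* — the
   derivative of the expected episode reward with respect to the specific
   pruning rate ``gamma_s`` at a reference policy — and label the lowest
   decile "human-regretful" and the highest decile "human-rewarding";
   select a fixed number of each at random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    HORIZON,
    LABEL_REGRETFUL,
    LABEL_REWARDING,
    LARGE_COST,
    N_ACTIONS,
    N_NODES,
    REWARD_VALUES,
    EnvBatch,
    Environment,
    RewardNetwork,
    Solution,
    _reachability,
    stack_environments,
)
from .planner import PruningParams, expected_reward_batch

__all__ = [
    "ClassifierConfig",
    "EnvironmentPool",
    "sample_network",
    "sample_networks_batch",
    "optimal_path",
    "optimal_rewards_batch",
    "structural_filter",
    "quartile_filter",
    "pruning_sensitivity",
    "classify_and_select",
    "build_pool",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    """Reference policy and selection sizes for sensitivity classification.

    The reference policy uses equal pruning rates ``gamma_g = gamma_s =
    ref_gamma`` and inverse temperature ``ref_beta``; the sensitivity is a
    central finite difference of the exact expected reward with step
    ``fd_step`` in ``gamma_s``.
    """

    ref_gamma: float = 0.35
    ref_beta: float = 0.03
    fd_step: float = 1e-4
    decile_fraction: float = 0.10
    n_select_per_type: int = 400

    def __post_init__(self) -> None:
        if not 0.0 <= self.ref_gamma <= 1.0:
            raise ValueError("ref_gamma outside [0, 1]")
        if self.ref_beta < 0.0:
            raise ValueError("ref_beta must be non-negative")
        if not 0.0 < self.fd_step < min(self.ref_gamma, 1.0 - self.ref_gamma):
            raise ValueError(
                "fd_step must keep gamma_s +/- fd_step inside [0, 1] "
                f"around ref_gamma={self.ref_gamma}"
            )


@dataclass
class EnvironmentPool:
    """A list of environments plus the stage counts of the pipeline run."""

    environments: list[Environment]
    counts: dict[str, int] = field(default_factory=dict)
    seed: int | None = None
    config: dict | None = None

    def __len__(self) -> int:
        return len(self.environments)

    def __iter__(self):
        return iter(self.environments)

    def by_id(self) -> dict[str, Environment]:
        return {e.env_id: e for e in self.environments}


# ---------------------------------------------------------------------------
# network sampling


def sample_networks_batch(
    n: int, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample ``n`` strongly connected networks.

    Returns ``(targets, rewards)`` arrays of shape ``(n, 6, 2)``.  Proposals
    draw, for every node, two distinct non-self targets uniformly and edge
    payoffs uniformly from the four-value set; proposals failing strong
    connectivity are rejected.
    """
    rng = np.random.default_rng(rng)
    reward_vals = np.array(REWARD_VALUES, dtype=np.int64)
    out_t = np.empty((n, N_NODES, N_ACTIONS), dtype=np.int64)
    out_r = np.empty((n, N_NODES, N_ACTIONS), dtype=np.int64)
    got = 0
    while got < n:
        b = max(256, int((n - got) * 1.8))
        # two distinct draws from the 5 non-self nodes, via partial argsort
        order = np.argsort(rng.random((b, N_NODES, N_NODES - 1)), axis=-1)[..., :2]
        src = np.arange(N_NODES)[None, :, None]
        targets = order + (order >= src)  # map 0..4 onto the 5 other nodes
        keep = _reachability(targets)
        k = min(int(keep.sum()), n - got)
        if k == 0:
            continue
        idx = np.flatnonzero(keep)[:k]
        out_t[got : got + k] = targets[idx]
        out_r[got : got + k] = reward_vals[rng.integers(0, 4, size=(b, N_NODES, N_ACTIONS))][idx]
        got += k
    return out_t, out_r


def sample_network(rng: np.random.Generator | int | None = None) -> RewardNetwork:
    """Sample one strongly connected reward network."""
    t, r = sample_networks_batch(1, rng)
    return RewardNetwork(t[0], r[0])


# ---------------------------------------------------------------------------
# optimal paths


def _optimal_q(
    targets: np.ndarray, rewards: np.ndarray, horizon: int = HORIZON
) -> np.ndarray:
    """Undiscounted max-reward Q values, shape ``(horizon, E, 6, 2)``."""
    e = targets.shape[0]
    q = np.empty((horizon, e, N_NODES, N_ACTIONS), dtype=np.int64)
    q[0] = rewards
    ei = np.arange(e)[:, None, None]
    for d in range(1, horizon):
        v_next = q[d - 1].max(axis=-1)
        q[d] = rewards + v_next[ei, targets]
    return q


def optimal_rewards_batch(
    targets: np.ndarray, rewards: np.ndarray, start: np.ndarray, horizon: int = HORIZON
) -> np.ndarray:
    """Maximum total reward of a ``horizon``-move walk from each start."""
    q = _optimal_q(targets, rewards, horizon)
    return q[horizon - 1][np.arange(targets.shape[0]), start].max(axis=-1)


def _canonical_paths_batch(
    targets: np.ndarray, rewards: np.ndarray, start: np.ndarray, horizon: int = HORIZON
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical optimal paths (ties -> lexicographically smallest node
    sequence), vectorized.

    Returns ``(states, actions, move_rewards)`` of shapes
    ``(E, horizon + 1)``, ``(E, horizon)``, ``(E, horizon)``.
    """
    e = targets.shape[0]
    q = _optimal_q(targets, rewards, horizon)
    ei = np.arange(e)
    states = np.empty((e, horizon + 1), dtype=np.int64)
    actions = np.empty((e, horizon), dtype=np.int64)
    move_rewards = np.empty((e, horizon), dtype=np.int64)
    states[:, 0] = start
    for step in range(horizon):
        d = horizon - 1 - step
        s = states[:, step]
        qs = q[d, ei, s]  # (E, 2)
        best = qs.max(axis=-1, keepdims=True)
        tgt = targets[ei, s]  # (E, 2)
        # among maximizing actions prefer the smaller target node: since the
        # two targets are distinct this yields the lexicographically
        # smallest optimal node sequence
        pref = np.where(qs == best, tgt, N_NODES)
        a = pref.argmin(axis=-1)
        actions[:, step] = a
        move_rewards[:, step] = rewards[ei, s, a]
        states[:, step + 1] = targets[ei, s, a]
    return states, actions, move_rewards


def optimal_path(env: Environment, horizon: int = HORIZON) -> Solution:
    """Reward-maximizing walk; among ties, the lexicographically smallest
    node sequence."""
    st, ac, rw = _canonical_paths_batch(
        env.targets[None], env.rewards[None], np.array([env.start]), horizon
    )
    return Solution(tuple(st[0]), tuple(ac[0]), tuple(rw[0]))


# ---------------------------------------------------------------------------
# filters


def _structural_mask(
    targets: np.ndarray,
    rewards: np.ndarray,
    start: np.ndarray,
    min_distinct_nodes: int = 4,
    min_nonmyopic: int = 4,
) -> np.ndarray:
    states, actions, _ = _canonical_paths_batch(targets, rewards, start)
    e = targets.shape[0]
    # distinct nodes visited by the optimal path (start included)
    sorted_states = np.sort(states, axis=1)
    n_distinct = 1 + (sorted_states[:, 1:] != sorted_states[:, :-1]).sum(axis=1)
    # steps at which the optimal move's immediate payoff <= the alternative's
    ei = np.arange(e)[:, None]
    step_states = states[:, :-1]
    r_taken = rewards[ei, step_states, actions]
    r_other = rewards[ei, step_states, 1 - actions]
    n_nonmyopic = (r_taken <= r_other).sum(axis=1)
    return (n_distinct >= min_distinct_nodes) & (n_nonmyopic >= min_nonmyopic)


def structural_filter(env: Environment) -> bool:
    """True iff the canonical optimal path visits >= 4 distinct nodes and has
    >= 4 non-myopic steps (optimal move's payoff <= the alternative's)."""
    return bool(
        _structural_mask(env.targets[None], env.rewards[None], np.array([env.start]))[0]
    )


def quartile_filter(pool: list[Environment]) -> list[Environment]:
    """Keep environments whose optimal reward lies within [Q1, Q3] of the
    pool (linear-interpolation quartiles, boundaries inclusive)."""
    if not pool:
        raise ValueError("quartile_filter: empty pool")
    vals = np.array([_require_opt(e) for e in pool], dtype=np.float64)
    q1, q3 = np.percentile(vals, [25.0, 75.0], method="linear")
    return [e for e, v in zip(pool, vals) if q1 <= v <= q3]


def _require_opt(env: Environment) -> int:
    if env.optimal_reward is None:
        env.optimal_reward = int(
            optimal_rewards_batch(
                env.targets[None], env.rewards[None], np.array([env.start])
            )[0]
        )
    return env.optimal_reward


# ---------------------------------------------------------------------------
# sensitivity classification


def sensitivities_batch(batch: EnvBatch, cfg: ClassifierConfig) -> np.ndarray:
    """Central-difference d E[reward] / d gamma_s at the reference policy."""
    lo = PruningParams(cfg.ref_gamma, cfg.ref_gamma - cfg.fd_step, cfg.ref_beta)
    hi = PruningParams(cfg.ref_gamma, cfg.ref_gamma + cfg.fd_step, cfg.ref_beta)
    er_lo = expected_reward_batch(batch.targets, batch.rewards, batch.start, lo)
    er_hi = expected_reward_batch(batch.targets, batch.rewards, batch.start, hi)
    return (er_hi - er_lo) / (2.0 * cfg.fd_step)


def pruning_sensitivity(env: Environment, cfg: ClassifierConfig | None = None) -> float:
    """Derivative of expected reward w.r.t. the specific pruning rate.

    Positive values mean aversive pruning *helps* in this environment
    (human-rewarding direction); negative values mean it hurts
    (human-regretful direction).
    """
    cfg = cfg or ClassifierConfig()
    if not 0.0 <= cfg.ref_gamma - cfg.fd_step <= 1.0 or not (
        0.0 <= cfg.ref_gamma + cfg.fd_step <= 1.0
    ):
        raise ValueError("gamma_s +/- fd_step leaves [0, 1]")
    batch = stack_environments([env])
    return float(sensitivities_batch(batch, cfg)[0])


def classify_and_select(
    pool: list[Environment],
    cfg: ClassifierConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[Environment]:
    """Label decile extremes of pruning sensitivity and draw a selection.

    The lowest ``decile_fraction`` of sensitivities is labeled
    human-regretful, the highest human-rewarding; ``n_select_per_type``
    environments are drawn uniformly from each.  Ranking uses a stable sort
    by ``(sensitivity, env_id)`` so ties are resolved deterministically.
    """
    cfg = cfg or ClassifierConfig()
    rng = np.random.default_rng(rng)
    if not pool:
        raise ValueError("classify_and_select: empty pool")
    missing = [e for e in pool if e.sensitivity is None]
    if missing:
        batch = stack_environments(missing)
        for e, s in zip(missing, sensitivities_batch(batch, cfg)):
            e.sensitivity = float(s)
    order = sorted(range(len(pool)), key=lambda i: (pool[i].sensitivity, pool[i].env_id))
    n_decile = int(np.floor(len(pool) * cfg.decile_fraction))
    if cfg.n_select_per_type > n_decile:
        raise ValueError(
            f"cannot select {cfg.n_select_per_type} per type from a decile of {n_decile}"
        )
    low = [pool[i] for i in order[:n_decile]]
    high = [pool[i] for i in order[-n_decile:]]
    pick_low = rng.choice(n_decile, size=cfg.n_select_per_type, replace=False)
    pick_high = rng.choice(n_decile, size=cfg.n_select_per_type, replace=False)
    selected = [low[i].with_label(LABEL_REGRETFUL) for i in sorted(pick_low)]
    selected += [high[i].with_label(LABEL_REWARDING) for i in sorted(pick_high)]
    return selected


# ---------------------------------------------------------------------------
# pipeline


def build_pool(
    n_networks: int,
    rng: np.random.Generator | int | None = None,
    min_distinct_nodes: int = 4,
    min_nonmyopic: int = 4,
) -> EnvironmentPool:
    """Sample networks, expand starts, and run the quartile and structural
    filters.  Stage counts are recorded in ``pool.counts``.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    rng = np.random.default_rng(rng)
    net_t, net_r = sample_networks_batch(n_networks, rng)
    # one candidate per (network, start)
    targets = np.repeat(net_t, N_NODES, axis=0)
    rewards = np.repeat(net_r, N_NODES, axis=0)
    start = np.tile(np.arange(N_NODES), n_networks)
    n_cand = targets.shape[0]
    opt = optimal_rewards_batch(targets, rewards, start)
    q1, q3 = np.percentile(opt.astype(np.float64), [25.0, 75.0], method="linear")
    keep_q = (opt >= q1) & (opt <= q3)
    n_quart = int(keep_q.sum())
    idx_q = np.flatnonzero(keep_q)
    keep_s = _structural_mask(
        targets[idx_q], rewards[idx_q], start[idx_q], min_distinct_nodes, min_nonmyopic
    )
    idx = idx_q[keep_s]
    environments = []
    for i in idx:
        net = RewardNetwork(targets[i], rewards[i])
        environments.append(
            Environment(
                net,
                int(start[i]),
                optimal_reward=int(opt[i]),
                env_id=f"n{i // N_NODES:06d}s{start[i]}",
            )
        )
    counts = {
        "networks": n_networks,
        "candidates": n_cand,
        "after_quartile_filter": n_quart,
        "after_structural_filter": len(environments),
    }
    logger.info("environment pool: %s", counts)
    return EnvironmentPool(environments, counts=counts)
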