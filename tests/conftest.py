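from __future__ import annotations

import numpy as np
import pytest

from prunechain.core import Environment, RewardNetwork
from prunechain.envgen import ClassifierConfig, build_pool, classify_and_select


@pytest.fixture(scope="session")
def env_pool():
    """Moderate filtered pool shared across tests (deterministic seed)."""
    return build_pool(2000, np.random.default_rng(20260921))


@pytest.fixture(scope="session")
def selection(env_pool):
    """Small labeled selection: 25 environments per type."""
    cfg = ClassifierConfig(n_select_per_type=25)
    return classify_and_select(
        env_pool.environments, cfg, np.random.default_rng(7)
    )


@pytest.fixture(scope="session")
def random_envs(env_pool):
    """100 unlabeled environments for oracle sweeps."""
    rng = np.random.default_rng(99)
    idx = rng.choice(len(env_pool.environments), size=100, replace=False)
    return [env_pool.environments[i] for i in idx]


def _cycle_trap_network() -> RewardNetwork:
    # Five-node reward cycle 0->1->2->3->4->0 paying 20 per move, with a
    # tempting 140 edge from every cycle node into trap node 5, whose only
    # exits cost -100.  Patience on the cycle is non-myopic at every step.
    targets = np.array(
        [[1, 5], [2, 5], [3, 5], [4, 5], [0, 5], [0, 1]], dtype=np.int64
    )
    rewards = np.array(
        [[20, 140], [20, 140], [20, 140], [20, 140], [20, 140], [-100, -100]],
        dtype=np.int64,
    )
    return RewardNetwork(targets, rewards)


@pytest.fixture()
def toy_env() -> Environment:
    """Hand-built cycle-with-trap environment (start node 0)."""
    return Environment(_cycle_trap_network(), start=0, env_id="toy-cycle-trap")


@pytest.fixture()
def two_node_loop_env() -> Environment:
    """Environment whose optimal path alternates between two nodes."""
    targets = np.array(
        [[1, 2], [0, 3], [0, 4], [0, 5], [0, 1], [0, 1]], dtype=np.int64
    )
    rewards = np.array(
        [[140, -100], [140, -100], [-20, -20], [-20, -20], [-20, -20], [-20, -20]],
        dtype=np.int64,
    )
    return Environment(RewardNetwork(targets, rewards), start=0, env_id="toy-loop")


@pytest.fixture()
def myopic_env() -> Environment:
    """Environment where the optimal move is strictly greedy at every step."""
    targets = np.array(
        [[(s + 1) % 6, (s + 2) % 6] for s in range(6)], dtype=np.int64
    )
    rewards = np.array([[140, -100]] * 6, dtype=np.int64)
    return Environment(RewardNetwork(targets, rewards), start=0, env_id="toy-myopic")


def make_uniform_reward_env(reward: int, start: int = 0) -> Environment:
    """Environment whose every edge carries the same payoff."""
    targets = np.array(
        [[(s + 1) % 6, (s + 2) % 6] for s in range(6)], dtype=np.int64
    )
    rewards = np.full((6, 2), reward, dtype=np.int64)
    return Environment(
        RewardNetwork(targets, rewards), start=start, env_id=f"uniform{reward}"
    )
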