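"""Core domain types: reward networks, environments and solutions.

A *reward network* is a directed graph on six nodes in which every node has
exactly two outgoing edges, each carrying one of four payoffs
(-100, -20, 20, 140).  A *network* together with a fixed starting node is an
*environment*; a play of an environment is a *solution* — a walk of eight
moves whose total reward is the sum of the edge payoffs.

Internally nodes are integer indices ``0..5``; the public labels are the
letters ``A``..``F`` (used in serialized node sequences such as
``"E-C-A-B-F-A-B-F-A"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

#: the four admissible edge payoffs
REWARD_VALUES = (-100, -20, 20, 140)

#: payoff treated as a "large cost" by the aversive-pruning model
LARGE_COST = -100

#: number of nodes in a network
N_NODES = 6

#: out-degree of every node
N_ACTIONS = 2

#: number of moves in a solution (the planning horizon)
HORIZON = 8

NODE_LABELS = tuple("ABCDEF")

LABEL_REWARDING = "human-rewarding"
LABEL_REGRETFUL = "human-regretful"
LABEL_UNCLASSIFIED = "unclassified"


def node_label(index: int) -> str:
    return NODE_LABELS[index]


def node_index(label: str) -> int:
    try:
        return NODE_LABELS.index(label)
    except ValueError:
        raise ValueError(f"unknown node label {label!r}") from None


@dataclass(frozen=True)
class RewardNetwork:
    """Directed 6-node reward network with out-degree 2.

    Parameters
    ----------
    targets
        Integer array of shape ``(6, 2)``; ``targets[s, a]`` is the node
        reached by taking action ``a`` in node ``s`` (the deterministic
        transition function).
    rewards
        Integer array of shape ``(6, 2)``; ``rewards[s, a]`` is the payoff
        of that move.
    """

    targets: np.ndarray
    rewards: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.targets, dtype=np.int64)
        r = np.asarray(self.rewards, dtype=np.int64)
        object.__setattr__(self, "targets", t)
        object.__setattr__(self, "rewards", r)
        validate_network(self)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return NODE_LABELS

    @property
    def edges(self) -> set[tuple[str, str, int]]:
        """Edge set as ``(source, target, reward)`` label triples."""
        return {
            (NODE_LABELS[s], NODE_LABELS[self.targets[s, a]], int(self.rewards[s, a]))
            for s in range(N_NODES)
            for a in range(N_ACTIONS)
        }

    def is_strongly_connected(self) -> bool:
        return bool(_reachability(self.targets[None])[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RewardNetwork):
            return NotImplemented
        return bool(
            np.array_equal(self.targets, other.targets)
            and np.array_equal(self.rewards, other.rewards)
        )

    def __hash__(self) -> int:
        return hash((self.targets.tobytes(), self.rewards.tobytes()))


def validate_network(net: RewardNetwork, *, require_connected: bool = False) -> None:
    """Raise ``ValueError`` on any violated network invariant."""
    t, r = net.targets, net.rewards
    if t.shape != (N_NODES, N_ACTIONS) or r.shape != (N_NODES, N_ACTIONS):
        raise ValueError(
            f"network arrays must have shape {(N_NODES, N_ACTIONS)}; "
            f"got targets {t.shape}, rewards {r.shape}"
        )
    if t.min() < 0 or t.max() >= N_NODES:
        raise ValueError("edge target outside node range")
    src = np.arange(N_NODES)[:, None]
    if np.any(t == src):
        raise ValueError("self-loop edge")
    if np.any(t[:, 0] == t[:, 1]):
        raise ValueError("parallel edges: the two out-edges of a node must differ")
    if not np.isin(r, REWARD_VALUES).all():
        bad = r[~np.isin(r, REWARD_VALUES)].flat[0]
        raise ValueError(f"reward {bad} not in {REWARD_VALUES}")
    if require_connected and not net.is_strongly_connected():
        raise ValueError("network is not strongly connected")


def _reachability(targets: np.ndarray) -> np.ndarray:
    """Strong connectivity for a batch of networks.

    ``targets`` has shape ``(B, 6, 2)``; returns a boolean vector of length
    ``B``.  Reachability is computed by boolean squaring of the adjacency
    matrix (paths up to length 8 suffice on 6 nodes).
    """
    b = targets.shape[0]
    adj = np.zeros((b, N_NODES, N_NODES), dtype=bool)
    bi = np.arange(b)[:, None]
    si = np.arange(N_NODES)[None, :]
    for a in range(N_ACTIONS):
        adj[bi, si, targets[:, :, a]] = True
    reach = adj | np.eye(N_NODES, dtype=bool)
    for _ in range(3):  # (I|A)^8 covers all simple paths on 6 nodes
        reach = np.matmul(reach, reach)
    return reach.all(axis=(1, 2))


@dataclass
class Environment:
    """A reward network with a fixed starting node and (optional) labels.

    ``optimal_reward`` caches the maximum total reward over all eight-move
    walks from ``start``; ``sensitivity`` caches the derivative of the
    expected reward with respect to the aversive-pruning rate at the
    reference policy (used to classify environments as human-rewarding or
    human-regretful).
    """

    network: RewardNetwork
    start: int
    label: str = LABEL_UNCLASSIFIED
    optimal_reward: int | None = None
    sensitivity: float | None = None
    env_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < N_NODES:
            raise ValueError(f"start node {self.start} outside 0..{N_NODES - 1}")
        if self.label not in (LABEL_REWARDING, LABEL_REGRETFUL, LABEL_UNCLASSIFIED):
            raise ValueError(f"unknown environment label {self.label!r}")

    @property
    def targets(self) -> np.ndarray:
        return self.network.targets

    @property
    def rewards(self) -> np.ndarray:
        return self.network.rewards

    def with_label(self, label: str) -> "Environment":
        return replace(self, label=label)


@dataclass(frozen=True)
class Solution:
    """An eight-move walk through an environment.

    ``states`` holds the nine visited nodes (start first), ``actions`` the
    action index in ``{0, 1}`` taken at each step, ``rewards`` the per-move
    payoffs.
    """

    states: tuple[int, ...]
    actions: tuple[int, ...]
    rewards: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.states) != HORIZON + 1 or len(self.actions) != HORIZON:
            raise ValueError("a solution has 8 moves over 9 visited nodes")
        if len(self.rewards) != HORIZON:
            raise ValueError("a solution carries one reward per move")

    @property
    def total_reward(self) -> int:
        return int(sum(self.rewards))

    @property
    def moves(self) -> tuple[tuple[int, int, int], ...]:
        """Moves as ``(source, target, reward)`` index triples."""
        return tuple(
            (self.states[i], self.states[i + 1], self.rewards[i])
            for i in range(HORIZON)
        )

    def path_str(self) -> str:
        return "-".join(NODE_LABELS[s] for s in self.states)

    @classmethod
    def from_actions(cls, env: Environment, actions: Sequence[int]) -> "Solution":
        """Build the solution induced by an action sequence from ``env.start``."""
        actions = tuple(int(a) for a in actions)
        states = [env.start]
        rewards = []
        for a in actions:
            s = states[-1]
            if a not in (0, 1):
                raise ValueError(f"action {a} not in (0, 1)")
            rewards.append(int(env.rewards[s, a]))
            states.append(int(env.targets[s, a]))
        return cls(tuple(states), actions, tuple(rewards))

    @classmethod
    def from_states(cls, env: Environment, states: Sequence[int]) -> "Solution":
        """Build a solution from a node sequence, validating every move."""
        states = tuple(int(s) for s in states)
        if len(states) != HORIZON + 1:
            raise ValueError("node sequence must have 9 nodes")
        if states[0] != env.start:
            raise ValueError(
                f"walk starts at {NODE_LABELS[states[0]]}, "
                f"environment starts at {NODE_LABELS[env.start]}"
            )
        actions = []
        for i in range(HORIZON):
            s, nxt = states[i], states[i + 1]
            matches = np.flatnonzero(env.targets[s] == nxt)
            if matches.size == 0:
                raise ValueError(
                    f"move {NODE_LABELS[s]}->{NODE_LABELS[nxt]} is not an edge"
                )
            actions.append(int(matches[0]))
        return cls.from_actions(env, actions)


def validate_solution(env: Environment, sol: Solution) -> None:
    """Raise ``ValueError`` unless ``sol`` is a valid walk through ``env``."""
    if sol.states[0] != env.start:
        raise ValueError("solution does not start at the environment's start node")
    for i, (s, a) in enumerate(zip(sol.states, sol.actions)):
        if int(env.targets[s, a]) != sol.states[i + 1]:
            raise ValueError(f"step {i + 1}: move is not an edge of the network")
        if int(env.rewards[s, a]) != sol.rewards[i]:
            raise ValueError(f"step {i + 1}: recorded reward mismatches the edge")


@dataclass
class EnvBatch:
    """Column-stacked arrays for a list of environments (vectorized kernels).

    ``targets`` and ``rewards`` have shape ``(E, 6, 2)``, ``start`` shape
    ``(E,)``.
    """

    targets: np.ndarray
    rewards: np.ndarray
    start: np.ndarray
    env_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.targets.shape[0]

    def __iter__(self) -> Iterator[Environment]:
        for i in range(len(self)):
            yield self.environment(i)

    def environment(self, i: int) -> Environment:
        net = RewardNetwork(self.targets[i], self.rewards[i])
        env_id = self.env_ids[i] if self.env_ids else ""
        return Environment(net, int(self.start[i]), env_id=env_id)


def stack_environments(envs: Sequence[Environment]) -> EnvBatch:
    if not envs:
        raise ValueError("cannot stack an empty environment list")
    return EnvBatch(
        targets=np.stack([e.targets for e in envs]),
        rewards=np.stack([e.rewards for e in envs]),
        start=np.array([e.start for e in envs], dtype=np.int64),
        env_ids=[e.env_id for e in envs],
    )
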