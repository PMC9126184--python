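"""Transmission-chain engine and synthetic cohort.

Simulates 8-generation transmission chains on classified environments in two
conditions: *human-only* (all eight generations are synthetic human players)
and *hybrid* (an algorithmic player replaces generation 2).  Each player
observes only the previous player's solution; generation 1 observes a
uniformly random solution.

Synthetic humans are generative stand-ins for the study cohort: they either
copy the observed solution wholesale — with a logistic propensity that
increases with the observed solution's (standardized) reward and decreases
with its number of large costs, the content bias measured in the experiment —
or innovate by sampling from the aversive-pruning softmax policy at the human
pilot parameters (gamma_g=0.20, gamma_s=0.45, beta=0.012).  A fixed fraction
of human attempts is invalid (timeouts in the experiment); invalid attempts
are excluded and the chain slot is replayed by a fresh participant.

The algorithmic player samples from a risk-seeking policy (gamma_g=0.5,
gamma_s=0.05, beta=0.0264) and applies a copy heuristic: it plays its own
sample iff that sample's total reward is greater than or equal to the
previous player's, otherwise it replays the previous solution exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .core import HORIZON, LARGE_COST, Environment, Solution, validate_solution
from .envgen import optimal_rewards_batch
from .planner import PolicyTable, PruningParams, policy

__all__ = [
    "AgentSpec",
    "GameRecord",
    "ExperimentDesign",
    "ChainResult",
    "ExperimentResult",
    "DEFAULT_HUMAN",
    "DEFAULT_ALGORITHM",
    "random_seed_solution",
    "algorithm_act",
    "synthetic_human_act",
    "run_chain",
    "run_experiment",
    "matching_moves",
    "count_large_costs",
]

logger = logging.getLogger(__name__)

CONDITION_HUMAN_ONLY = "human-only"
CONDITION_HYBRID = "hybrid"
ALGORITHM_GENERATION = 2


@dataclass(frozen=True)
class AgentSpec:
    """Behavioural parameters of one player type.

    ``copy_bias = (intercept, reward_coefficient, large_cost_coefficient)``
    parameterizes the human whole-solution copy propensity
    ``logistic(b0 + b1 * z(prev_total) + b2 * n_large_costs(prev))``;
    algorithm agents ignore it and use the deterministic copy heuristic.
    ``invalid_rate`` is the probability that a human attempt is invalid.
    """

    player_type: str
    params: PruningParams
    copy_bias: tuple[float, float, float] | None = None
    invalid_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.player_type not in ("human", "algorithm"):
            raise ValueError(f"unknown player_type {self.player_type!r}")
        if not 0.0 <= self.invalid_rate <= 1.0:
            raise ValueError("invalid_rate outside [0, 1]")


# Pilot-study human parameters; copy-bias slope coefficients are the measured
# content-bias effects (reward 0.394 per SD, large costs -0.040), with the
# intercept set so the baseline copy propensity is ~0.3.  Invalid rate 9%.
DEFAULT_HUMAN = AgentSpec(
    "human",
    PruningParams(gamma_g=0.20, gamma_s=0.45, beta=0.012),
    copy_bias=(math.log(0.3 / 0.7), 0.394, -0.040),
    invalid_rate=0.09,
)

# Risk-seeking algorithm: inverted pruning bias, beta tuned to human-level
# mean performance.
DEFAULT_ALGORITHM = AgentSpec(
    "algorithm",
    PruningParams(gamma_g=0.5, gamma_s=0.05, beta=0.0264),
)


@dataclass
class GameRecord:
    """One play (or invalid attempt) within a transmission chain."""

    chain_id: str
    environment_id: str
    condition: str
    environment_type: str
    generation: int
    player_type: str
    participant_id: str
    solution: Solution
    total_reward: int
    valid: bool
    n_large_costs: int
    matches_prev: int
    matches_gen2: int = -1  # filled once the chain's generation 2 is known
    is_optimal: bool = False
    copied: bool = False
    #: the algorithm's own policy sample, kept also when the copy branch
    #: replays the predecessor (None for human records)
    own_solution: Solution | None = None


@dataclass
class ExperimentDesign:
    """Layout of a full simulated cohort.

    Every environment appears in exactly two chains (one per condition);
    participants are assigned round-robin under the constraints that nobody
    plays the same environment twice and nobody exceeds ``max_rounds``.
    """

    environments: list[Environment]
    generations: int = HORIZON
    n_participants: int = 177
    max_rounds: int = 80
    human: AgentSpec = DEFAULT_HUMAN
    algorithm: AgentSpec = DEFAULT_ALGORITHM

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.n_participants < 1:
            raise ValueError("participant pool must be non-empty")


# ---------------------------------------------------------------------------
# solution-level helpers


def count_large_costs(sol: Solution) -> int:
    """Number of moves carrying the large-cost payoff (-100)."""
    return sum(1 for r in sol.rewards if r == LARGE_COST)


def matching_moves(a: Solution, b: Solution, mode: str = "aligned") -> int:
    """Number of moves two solutions share.

    ``aligned`` (default) counts step positions at which both solutions
    traverse the same directed edge; ``unordered`` counts the multiset
    intersection of the two edge sequences regardless of position.
    """
    if a.states[0] != b.states[0]:
        raise ValueError("solutions start at different nodes; environments differ")
    if mode == "aligned":
        return sum(
            1
            for i in range(HORIZON)
            if a.states[i] == b.states[i] and a.states[i + 1] == b.states[i + 1]
        )
    if mode == "unordered":
        from collections import Counter

        ca = Counter((a.states[i], a.states[i + 1]) for i in range(HORIZON))
        cb = Counter((b.states[i], b.states[i + 1]) for i in range(HORIZON))
        return sum((ca & cb).values())
    raise ValueError(f"unknown matching mode {mode!r}")


def random_seed_solution(
    env: Environment, rng: np.random.Generator | int | None = None
) -> Solution:
    """Uniformly random eight-move walk (each move a fair coin flip)."""
    rng = np.random.default_rng(rng)
    return Solution.from_actions(env, rng.integers(0, 2, size=HORIZON))


# ---------------------------------------------------------------------------
# agents


class _PolicyCache:
    """Memoizes per-(environment, params) policy tables within a run."""

    def __init__(self) -> None:
        self._cache: dict[tuple[str, PruningParams], PolicyTable] = {}

    def get(self, env: Environment, params: PruningParams) -> PolicyTable:
        key = (env.env_id or str(id(env)), params)
        pol = self._cache.get(key)
        if pol is None:
            pol = policy(env, params)
            self._cache[key] = pol
        return pol


def _sample_from_policy(
    env: Environment, pol: PolicyTable, rng: np.random.Generator
) -> Solution:
    state = env.start
    actions = []
    for step in range(HORIZON):
        p1 = pol.probs[HORIZON - 1 - step, state, 1]
        a = int(rng.random() < p1)
        actions.append(a)
        state = int(env.targets[state, a])
    return Solution.from_actions(env, actions)


class AlgorithmMove(NamedTuple):
    """Outcome of one algorithmic play."""

    solution: Solution  #: the solution actually played
    copied: bool  #: True when the copy branch replayed the predecessor
    own_sample: Solution  #: the policy sample, whether or not it was played


def algorithm_act(
    env: Environment,
    prev: Solution,
    spec: AgentSpec = DEFAULT_ALGORITHM,
    rng: np.random.Generator | int | None = None,
    _cache: _PolicyCache | None = None,
) -> AlgorithmMove:
    """Algorithmic play with the copy heuristic.

    Samples one solution from the algorithm's policy and plays it iff its
    total reward >= the previous player's; otherwise replays ``prev``
    exactly.  The returned move records which branch was taken and keeps
    the raw policy sample (played solutions are conditioned on beating the
    predecessor, so only the raw samples are an unbiased draw from the
    algorithm's policy).
    """
    rng = np.random.default_rng(rng)
    validate_solution(env, prev)
    pol = (_cache or _PolicyCache()).get(env, spec.params)
    own = _sample_from_policy(env, pol, rng)
    if own.total_reward >= prev.total_reward:
        return AlgorithmMove(own, False, own)
    return AlgorithmMove(prev, True, own)


class RewardNormalizer:
    """Running mean/SD of solution rewards within the current simulation,
    used to standardize the observed solution's reward in the human copy
    propensity.  Returns 0 until two values have been seen."""

    def __init__(self) -> None:
        self.n = 0
        self._mean = 0.0
        self._m2 = 0.0

    def update(self, value: float) -> None:
        self.n += 1
        delta = value - self._mean
        self._mean += delta / self.n
        self._m2 += delta * (value - self._mean)

    def z(self, value: float) -> float:
        if self.n < 2:
            return 0.0
        sd = math.sqrt(self._m2 / (self.n - 1))
        return 0.0 if sd == 0.0 else (value - self._mean) / sd


def copy_probability(
    prev: Solution, spec: AgentSpec, normalizer: RewardNormalizer | None = None
) -> float:
    """Logistic whole-solution copy propensity of a synthetic human."""
    if spec.copy_bias is None:
        raise ValueError("agent has no copy_bias (not a synthetic human)")
    b0, b_reward, b_large = spec.copy_bias
    z = normalizer.z(prev.total_reward) if normalizer is not None else 0.0
    logit = b0 + b_reward * z + b_large * count_large_costs(prev)
    if logit == -math.inf:
        return 0.0
    return 1.0 / (1.0 + math.exp(-logit))


def synthetic_human_act(
    env: Environment,
    prev: Solution,
    spec: AgentSpec = DEFAULT_HUMAN,
    rng: np.random.Generator | int | None = None,
    normalizer: RewardNormalizer | None = None,
    _cache: _PolicyCache | None = None,
) -> tuple[Solution, bool]:
    """One synthetic-human attempt: copy wholesale or innovate.

    With probability ``copy_probability(prev)`` returns an exact copy of
    ``prev``; otherwise samples from the human pruning policy.  Returns
    ``(solution, copied)``.  Invalid attempts are handled by the chain
    engine, which redraws the slot with a fresh participant.
    """
    rng = np.random.default_rng(rng)
    validate_solution(env, prev)
    if rng.random() < copy_probability(prev, spec, normalizer):
        return prev, True
    pol = (_cache or _PolicyCache()).get(env, spec.params)
    return _sample_from_policy(env, pol, rng), False


# ---------------------------------------------------------------------------
# chains


@dataclass
class ChainResult:
    """Eight valid records of one chain plus the excluded invalid attempts."""

    records: list[GameRecord]
    invalid_attempts: list[GameRecord] = field(default_factory=list)

    @property
    def algorithm_copied(self) -> bool | None:
        for rec in self.records:
            if rec.player_type == "algorithm":
                return rec.copied
        return None


class _ParticipantPool:
    """Round-robin participant assignment honouring the design constraints:
    no participant plays the same environment twice or more than
    ``max_rounds`` rounds."""

    def __init__(self, n: int, max_rounds: int) -> None:
        self.ids = [f"p{i:03d}" for i in range(n)]
        self.max_rounds = max_rounds
        self.rounds = dict.fromkeys(self.ids, 0)
        self.played: dict[str, set[str]] = {pid: set() for pid in self.ids}
        self._ptr = 0

    def assign(self, env_id: str) -> str:
        n = len(self.ids)
        for off in range(n):
            pid = self.ids[(self._ptr + off) % n]
            if self.rounds[pid] < self.max_rounds and env_id not in self.played[pid]:
                self._ptr = (self._ptr + off + 1) % n
                self.rounds[pid] += 1
                self.played[pid].add(env_id)
                return pid
        raise RuntimeError(
            "participant pool exhausted: no participant can play "
            f"environment {env_id} within the round limit"
        )


def _mk_record(
    env: Environment,
    chain_id: str,
    condition: str,
    generation: int,
    player_type: str,
    participant_id: str,
    sol: Solution,
    prev: Solution,
    valid: bool,
    copied: bool,
    optimal_reward: int,
) -> GameRecord:
    return GameRecord(
        chain_id=chain_id,
        environment_id=env.env_id,
        condition=condition,
        environment_type=env.label,
        generation=generation,
        player_type=player_type,
        participant_id=participant_id,
        solution=sol,
        total_reward=sol.total_reward,
        valid=valid,
        n_large_costs=count_large_costs(sol),
        matches_prev=matching_moves(sol, prev),
        is_optimal=sol.total_reward == optimal_reward,
        copied=copied,
    )


def run_chain(
    env: Environment,
    condition: str,
    rng: np.random.Generator | int | None = None,
    human: AgentSpec = DEFAULT_HUMAN,
    algorithm: AgentSpec = DEFAULT_ALGORITHM,
    chain_id: str | None = None,
    generations: int = HORIZON,
    participants: _ParticipantPool | None = None,
    normalizer: RewardNormalizer | None = None,
    cache: _PolicyCache | None = None,
) -> ChainResult:
    """Simulate one transmission chain.

    Generation 1 observes a uniformly random seed solution; in the hybrid
    condition generation 2 is the algorithm, every other slot a synthetic
    human.  An invalid human attempt is recorded (``valid=False``), excluded
    from the lineage, and the slot is replayed by a fresh participant.
    """
    if condition not in (CONDITION_HUMAN_ONLY, CONDITION_HYBRID):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(rng)
    cache = cache or _PolicyCache()
    chain_id = chain_id or f"{env.env_id}-{'hy' if condition == CONDITION_HYBRID else 'ho'}"
    opt = env.optimal_reward
    if opt is None:
        opt = int(
            optimal_rewards_batch(env.targets[None], env.rewards[None], np.array([env.start]))[0]
        )
    records: list[GameRecord] = []
    invalid: list[GameRecord] = []
    prev = random_seed_solution(env, rng)
    attempt_serial = 0

    def next_pid() -> str:
        nonlocal attempt_serial
        if participants is not None:
            return participants.assign(env.env_id)
        attempt_serial += 1
        return f"{chain_id}-a{attempt_serial:02d}"

    for gen in range(1, generations + 1):
        if condition == CONDITION_HYBRID and gen == ALGORITHM_GENERATION:
            move = algorithm_act(env, prev, algorithm, rng, _cache=cache)
            rec = _mk_record(env, chain_id, condition, gen, "algorithm", "algorithm",
                             move.solution, prev, True, move.copied, opt)
            rec.own_solution = move.own_sample
            records.append(rec)
        else:
            while True:
                pid = next_pid()
                sol, copied = synthetic_human_act(
                    env, prev, human, rng, normalizer, _cache=cache
                )
                if rng.random() < human.invalid_rate:
                    invalid.append(
                        _mk_record(env, chain_id, condition, gen, "human", pid,
                                   sol, prev, False, copied, opt)
                    )
                    continue  # slot reopened for a fresh participant
                break
            records.append(
                _mk_record(env, chain_id, condition, gen, "human", pid,
                           sol, prev, True, copied, opt)
            )
        prev = records[-1].solution
        if normalizer is not None:
            normalizer.update(prev.total_reward)
    gen2 = records[ALGORITHM_GENERATION - 1].solution if generations >= 2 else None
    for rec in records + invalid:
        rec.matches_gen2 = matching_moves(rec.solution, gen2) if gen2 is not None else -1
    return ChainResult(records, invalid)


@dataclass
class ExperimentResult:
    """All valid records of a simulated cohort plus excluded attempts and
    consistency counts."""

    records: list[GameRecord]
    invalid_attempts: list[GameRecord]
    counts: dict[str, int]

    @property
    def invalid_rate(self) -> float:
        n_att = len(self.invalid_attempts) + sum(
            1 for r in self.records if r.player_type == "human"
        )
        return len(self.invalid_attempts) / n_att if n_att else 0.0

    def algorithm_copy_rate(self, environment_type: str | None = None) -> float:
        algo = [
            r
            for r in self.records
            if r.player_type == "algorithm"
            and (environment_type is None or r.environment_type == environment_type)
        ]
        if not algo:
            raise ValueError("no algorithm records in this selection")
        return sum(r.copied for r in algo) / len(algo)


def run_experiment(
    design: ExperimentDesign, rng: np.random.Generator | int | None = None
) -> ExperimentResult:
    """Simulate the full 2 x 2 cohort: two chains (one per condition) for
    every environment."""
    rng = np.random.default_rng(rng)
    pool = _ParticipantPool(design.n_participants, design.max_rounds)
    normalizer = RewardNormalizer()
    cache = _PolicyCache()
    records: list[GameRecord] = []
    invalid: list[GameRecord] = []
    for env in design.environments:
        if not env.env_id:
            raise ValueError("environments in a design need env_id set")
        for condition in (CONDITION_HUMAN_ONLY, CONDITION_HYBRID):
            res = run_chain(
                env,
                condition,
                rng,
                human=design.human,
                algorithm=design.algorithm,
                generations=design.generations,
                participants=pool,
                normalizer=normalizer,
                cache=cache,
            )
            records.extend(res.records)
            invalid.extend(res.invalid_attempts)
    n_algo = sum(1 for r in records if r.player_type == "algorithm")
    counts = {
        "environments": len(design.environments),
        "chains": 2 * len(design.environments),
        "games": len(records),
        "algorithm_games": n_algo,
        "invalid_attempts": len(invalid),
    }
    logger.info("experiment: %s", counts)
    return ExperimentResult(records, invalid, counts)
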