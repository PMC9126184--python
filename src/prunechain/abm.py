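"""Abstract agent-based model of content-biased hybrid transmission.

Task solutions are points ``(s_g, s_s)`` in a two-dimensional quality space:
``s_g`` is the general quality of a solution and ``s_s`` its specialization
— how adapted it is to a particular environment type.  The realized reward
in an environment of type ``tau`` (+1 favours the human specialization, -1
the algorithmic one) is ``s_g + tau * s_s``.

Human and algorithmic agents are modelled symmetrically and differ only in
the sign of their specialization bias (+1 human, -1 algorithm).  At each
generation an agent assesses a *perceived quality* of the observed solution
— the realized reward alone for a *utilitarian* content bias, or with an
additional bonus ``w * bias_sign * s_s`` for matching the agent's own
specialization under an *adapted* content bias — and copies the solution
exactly with logistic probability ``sigmoid(kappa * (quality - q0))``,
otherwise innovating by sampling ``s_g ~ N(0, 1)`` and
``s_s ~ N(b * bias_sign, 1)``.

Chains of eight generations start from the neutral solution ``(0, 0)``.
Compositions: ``human-only``, ``algorithm-only``, ``single-algorithm`` (the
experiment's hybrid layout: an algorithm at generation 2 only) and
``random-mixed`` (each slot human or algorithm with probability 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HORIZON

__all__ = [
    "ABMSolution",
    "ABMAgent",
    "ABMConfig",
    "NEUTRAL_SOLUTION",
    "agent_pair",
    "innovate",
    "realized_reward",
    "perceived_quality",
    "abm_step",
    "run_abm",
    "COMPOSITIONS",
]

COMPOSITIONS = ("human-only", "algorithm-only", "single-algorithm", "random-mixed")
CONTENT_BIASES = ("utilitarian", "adapted")

ENV_HUMAN_REWARDING = +1
ENV_HUMAN_REGRETFUL = -1


@dataclass(frozen=True)
class ABMSolution:
    """A solution as a point in the (general quality, specialization) plane."""

    s_g: float
    s_s: float


NEUTRAL_SOLUTION = ABMSolution(0.0, 0.0)


@dataclass(frozen=True)
class ABMAgent:
    """One agent type.

    ``bias_sign`` is +1 for human-like and -1 for algorithmic agents; all
    other parameters are shared between the two types (the model is
    symmetric).
    """

    agent_type: str
    bias_sign: int
    content_bias: str = "utilitarian"
    innovation_shift: float = 1.0  # b: mean of the specialization draw
    adaptation_weight: float = 1.0  # w: bonus for matching own specialization
    copy_steepness: float = 0.4  # kappa
    copy_threshold: float = 2.5  # q0

    def __post_init__(self) -> None:
        if self.bias_sign not in (+1, -1):
            raise ValueError("bias_sign must be +1 or -1")
        if self.content_bias not in CONTENT_BIASES:
            raise ValueError(f"unknown content bias {self.content_bias!r}")
        if self.innovation_shift < 0 or self.adaptation_weight < 0:
            raise ValueError("innovation_shift and adaptation_weight must be >= 0")
        if self.copy_steepness <= 0:
            raise ValueError("copy_steepness must be > 0")


def agent_pair(
    content_bias: str = "utilitarian",
    innovation_shift: float = 1.0,
    adaptation_weight: float = 1.0,
    copy_steepness: float = 0.4,
    copy_threshold: float = 2.5,
) -> tuple[ABMAgent, ABMAgent]:
    """Symmetric (human, algorithm) pair differing only in bias sign."""
    mk = lambda t, s: ABMAgent(
        t, s, content_bias, innovation_shift, adaptation_weight,
        copy_steepness, copy_threshold,
    )
    return mk("human", +1), mk("algorithm", -1)


@dataclass(frozen=True)
class ABMConfig:
    """One simulated condition of the agent-based model."""

    env_type: int  # +1 human-rewarding, -1 human-regretful
    composition: str = "single-algorithm"
    generations: int = HORIZON
    n_chains: int = 12_500

    def __post_init__(self) -> None:
        if self.env_type not in (ENV_HUMAN_REWARDING, ENV_HUMAN_REGRETFUL):
            raise ValueError("env_type must be +1 or -1")
        if self.composition not in COMPOSITIONS:
            raise ValueError(f"unknown composition {self.composition!r}")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


def innovate(agent: ABMAgent, rng: np.random.Generator | int | None = None) -> ABMSolution:
    """Sample a fresh solution skewed towards the agent's specialization."""
    rng = np.random.default_rng(rng)
    return ABMSolution(
        s_g=float(rng.normal(0.0, 1.0)),
        s_s=float(rng.normal(agent.innovation_shift * agent.bias_sign, 1.0)),
    )


def realized_reward(sol: ABMSolution, env_type: int) -> float:
    """Reward actually earned by a solution in an environment of ``env_type``."""
    if env_type not in (ENV_HUMAN_REWARDING, ENV_HUMAN_REGRETFUL):
        raise ValueError("env_type must be +1 or -1")
    return sol.s_g + env_type * sol.s_s


def perceived_quality(agent: ABMAgent, sol: ABMSolution, env_type: int) -> float:
    """Quality the agent attributes to an observed solution."""
    quality = realized_reward(sol, env_type)
    if agent.content_bias == "adapted":
        quality += agent.adaptation_weight * agent.bias_sign * sol.s_s
    return quality


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def abm_step(
    agent: ABMAgent,
    prev: ABMSolution,
    env_type: int,
    rng: np.random.Generator | int | None = None,
) -> ABMSolution:
    """Copy the observed solution or innovate, by perceived quality."""
    rng = np.random.default_rng(rng)
    q = perceived_quality(agent, prev, env_type)
    p_copy = float(_sigmoid(agent.copy_steepness * (q - agent.copy_threshold)))
    if rng.random() < p_copy:
        return prev
    return innovate(agent, rng)


def _bias_signs(
    config: ABMConfig, generation: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-chain bias sign of the agent playing ``generation`` (1-based)."""
    n = config.n_chains
    if config.composition == "human-only":
        return np.full(n, +1, dtype=np.int64)
    if config.composition == "algorithm-only":
        return np.full(n, -1, dtype=np.int64)
    if config.composition == "single-algorithm":
        return np.full(n, -1 if generation == 2 else +1, dtype=np.int64)
    return np.where(rng.random(n) < 0.5, +1, -1)  # random-mixed


def run_abm(
    config: ABMConfig,
    agents: tuple[ABMAgent, ABMAgent] | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate ``n_chains`` independent chains of one condition.

    Returns one row per generation with the mean realized reward of the
    solutions played at that generation and its Monte-Carlo standard error.
    """
    rng = np.random.default_rng(rng)
    human, algorithm = agents if agents is not None else agent_pair()
    if (
        human.bias_sign != +1
        or algorithm.bias_sign != -1
        or (human.content_bias, human.innovation_shift, human.adaptation_weight,
            human.copy_steepness, human.copy_threshold)
        != (algorithm.content_bias, algorithm.innovation_shift,
            algorithm.adaptation_weight, algorithm.copy_steepness,
            algorithm.copy_threshold)
    ):
        raise ValueError("human and algorithm agents must differ only in bias sign")
    n = config.n_chains
    tau = config.env_type
    sg = np.zeros(n)
    ss = np.zeros(n)  # neutral initial solution
    rows = []
    for gen in range(1, config.generations + 1):
        sign = _bias_signs(config, gen, rng)
        quality = sg + tau * ss
        if human.content_bias == "adapted":
            quality = quality + human.adaptation_weight * sign * ss
        p_copy = _sigmoid(human.copy_steepness * (quality - human.copy_threshold))
        copy_mask = rng.random(n) < p_copy
        new_sg = rng.normal(0.0, 1.0, size=n)
        new_ss = rng.normal(human.innovation_shift * sign, 1.0, size=n)
        sg = np.where(copy_mask, sg, new_sg)
        ss = np.where(copy_mask, ss, new_ss)
        reward = sg + tau * ss
        rows.append(
            dict(
                composition=config.composition,
                content_bias=human.content_bias,
                env_type=tau,
                generation=gen,
                mean_reward=float(reward.mean()),
                mc_se=float(reward.std(ddof=1) / np.sqrt(n)),
                copy_rate=float(copy_mask.mean()),
                n_chains=n,
            )
        )
    return pd.DataFrame(rows)
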