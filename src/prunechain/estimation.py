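"""Maximum-likelihood fitting of the aversive-pruning model.

Fits ``(gamma_g, gamma_s, beta)`` by maximizing the softmax-policy
log-likelihood of observed solutions, with multi-start bounded local
optimization.  Uncertainty comes from a nonparametric bootstrap over games
(resampling whole solutions with replacement): percentile confidence
intervals, and p-values computed as the fraction of bootstrap fits
satisfying a null hypothesis.

Also provides the per-generation / per-condition fitting sweep used to track
how behaviour changes along transmission chains, the inverse-temperature
calibration that matches a policy's mean expected reward to a target
performance, and descriptive summary tables of a simulated cohort.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .chains import GameRecord
from .core import Environment, Solution, stack_environments
from .planner import GameStack, PruningParams, expected_reward_batch

__all__ = [
    "FitResult",
    "BootstrapResult",
    "CellFit",
    "fit_mle",
    "bootstrap_fit",
    "fits_by_generation_condition",
    "calibrate_beta",
    "summary_report",
    "DEFAULT_BOUNDS",
    "DEFAULT_STARTS",
]

logger = logging.getLogger(__name__)

#: box bounds for (gamma_g, gamma_s, beta)
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = ((0.0, 1.0), (0.0, 1.0), (0.0, 1.0))

#: 3 x 3 x 3 multi-start grid over (gamma_g, gamma_s, beta)
DEFAULT_STARTS: tuple[tuple[float, float, float], ...] = tuple(
    itertools.product((0.1, 0.5, 0.9), (0.1, 0.5, 0.9), (0.005, 0.02, 0.05))
)

_PARAM_NAMES = ("gamma_g", "gamma_s", "beta")


@dataclass
class FitResult:
    """Point estimate of the pruning parameters for one set of games."""

    gamma_g_hat: float
    gamma_s_hat: float
    beta_hat: float
    loglik: float
    converged: bool
    n_games: int
    identifiable: bool

    @property
    def params(self) -> PruningParams:
        return PruningParams(self.gamma_g_hat, self.gamma_s_hat, self.beta_hat)

    def estimate(self, name: str) -> float:
        return {
            "gamma_g": self.gamma_g_hat,
            "gamma_s": self.gamma_s_hat,
            "beta": self.beta_hat,
        }[name]


@dataclass
class BootstrapResult:
    """Point fit plus bootstrap resampling uncertainty."""

    point: FitResult
    samples: list[FitResult]
    ci: dict[str, tuple[float, float]]
    p_values: dict[str, float] = field(default_factory=dict)

    def sample_array(self, name: str) -> np.ndarray:
        return np.array([s.estimate(name) for s in self.samples])


def _as_stack(games: Sequence[tuple[Environment, Solution]] | GameStack) -> GameStack:
    return games if isinstance(games, GameStack) else GameStack(list(games))


def fit_mle(
    games: Sequence[tuple[Environment, Solution]] | GameStack,
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS,
    starts: Sequence[tuple[float, float, float]] | None = None,
) -> FitResult:
    """Maximum-likelihood estimate of ``(gamma_g, gamma_s, beta)``.

    Runs bounded L-BFGS-B from every point of ``starts`` (default: the
    3 x 3 x 3 grid) and keeps the best local optimum.  The fit is flagged
    non-identifiable when the likelihood does not improve on the flat
    ``beta = 0`` model, in which case the pruning rates carry no
    information.
    """
    stack = _as_stack(games)
    if stack.n_games < 1:
        raise ValueError("fit_mle needs at least one valid game")
    starts = starts if starts is not None else DEFAULT_STARTS
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def nll(x: np.ndarray) -> float:
        g, s, b = np.clip(x, lo, hi)
        return -stack.loglik(PruningParams(g, s, b))

    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            nll,
            np.clip(np.asarray(x0, dtype=float), lo, hi),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-6, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    g, s, b = np.clip(best.x, lo, hi)
    loglik = -float(best.fun)
    loglik_flat = -stack.n_moves * np.log(2.0)  # beta = 0: uniform policy
    identifiable = loglik > loglik_flat + 1e-6 and b > 1e-6
    return FitResult(
        gamma_g_hat=float(g),
        gamma_s_hat=float(s),
        beta_hat=float(b),
        loglik=loglik,
        converged=converged,
        n_games=stack.n_games,
        identifiable=identifiable,
    )


def bootstrap_fit(
    games: Sequence[tuple[Environment, Solution]] | GameStack,
    n_boot: int = 100,
    hypotheses: Mapping[str, Callable[[FitResult], bool]] | None = None,
    rng: np.random.Generator | int | None = None,
    ci_level: float = 0.95,
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS,
    starts: Sequence[tuple[float, float, float]] | None = None,
) -> BootstrapResult:
    """Bootstrap the MLE over games.

    Resamples whole games with replacement ``n_boot`` times and refits each
    resample (started from the point estimate, which makes the refits fast
    and stable).  ``ci`` holds percentile intervals; ``p_values[name]`` is
    the fraction of bootstrap fits satisfying the null hypothesis
    ``hypotheses[name]`` (a predicate on a :class:`FitResult`).
    """
    rng = np.random.default_rng(rng)
    stack = _as_stack(games)
    point = fit_mle(stack, bounds=bounds, starts=starts)
    x_hat = (point.gamma_g_hat, point.gamma_s_hat, point.beta_hat)
    samples: list[FitResult] = []
    for _ in range(n_boot):
        idx = rng.integers(0, stack.n_games, size=stack.n_games)
        samples.append(fit_mle(stack.subset(idx), bounds=bounds, starts=[x_hat]))
    alpha = (1.0 - ci_level) / 2.0
    ci = {}
    for name in _PARAM_NAMES:
        vals = np.array([s.estimate(name) for s in samples])
        ci[name] = tuple(np.percentile(vals, [100 * alpha, 100 * (1 - alpha)]))
    p_values = {}
    for name, null in (hypotheses or {}).items():
        p_values[name] = float(np.mean([null(s) for s in samples]))
    return BootstrapResult(point=point, samples=samples, ci=ci, p_values=p_values)


# ---------------------------------------------------------------------------
# per-generation / per-condition sweep


@dataclass
class CellFit:
    """Bootstrap fit for one (generation, condition, environment type) cell."""

    generation: int
    condition: str
    environment_type: str
    result: BootstrapResult | None
    n_games: int
    note: str = ""


def _games_from_records(
    records: Sequence[GameRecord], envs_by_id: Mapping[str, Environment]
) -> list[tuple[Environment, Solution]]:
    games = []
    for rec in records:
        env = envs_by_id.get(rec.environment_id)
        if env is None:
            raise KeyError(f"no environment with id {rec.environment_id!r}")
        games.append((env, rec.solution))
    return games


def fits_by_generation_condition(
    records: Sequence[GameRecord],
    envs_by_id: Mapping[str, Environment],
    n_boot: int = 100,
    rng: np.random.Generator | int | None = None,
    generations: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Independent bootstrap fits per (generation, condition, env type) cell.

    Returns a tidy frame with one row per cell and parameter (estimate,
    ci_low, ci_high, n_games), including rows for the between-condition
    difference (hybrid minus human-only) per generation and environment
    type, whose CIs come from pairing the two cells' independent bootstrap
    replicates.  Empty cells are flagged in the ``note`` column, not fatal.
    """
    rng = np.random.default_rng(rng)
    recs = [r for r in records if r.valid]
    gens = sorted({r.generation for r in recs}) if generations is None else list(generations)
    conditions = sorted({r.condition for r in recs})
    env_types = sorted({r.environment_type for r in recs})
    cells: dict[tuple[int, str, str], CellFit] = {}
    for gen, cond, etype in itertools.product(gens, conditions, env_types):
        sel = [
            r
            for r in recs
            if r.generation == gen and r.condition == cond and r.environment_type == etype
        ]
        if not sel:
            cells[gen, cond, etype] = CellFit(gen, cond, etype, None, 0, "empty cell")
            continue
        result = bootstrap_fit(
            _games_from_records(sel, envs_by_id), n_boot=n_boot, rng=rng
        )
        cells[gen, cond, etype] = CellFit(gen, cond, etype, result, len(sel))
    rows = []
    for (gen, cond, etype), cell in cells.items():
        for name in _PARAM_NAMES:
            if cell.result is None:
                rows.append(
                    dict(generation=gen, condition=cond, environment_type=etype,
                         parameter=name, estimate=np.nan, ci_low=np.nan,
                         ci_high=np.nan, n_games=0, note=cell.note)
                )
            else:
                lo, hi = cell.result.ci[name]
                rows.append(
                    dict(generation=gen, condition=cond, environment_type=etype,
                         parameter=name, estimate=cell.result.point.estimate(name),
                         ci_low=lo, ci_high=hi, n_games=cell.n_games, note="")
                )
    # between-condition differences (hybrid - human-only), paired replicates
    if {"hybrid", "human-only"} <= set(conditions):
        for gen, etype in itertools.product(gens, env_types):
            a = cells.get((gen, "hybrid", etype))
            b = cells.get((gen, "human-only", etype))
            if not a or not b or a.result is None or b.result is None:
                continue
            for name in _PARAM_NAMES:
                da = a.result.sample_array(name)
                db = b.result.sample_array(name)
                n = min(da.size, db.size)
                diff = da[:n] - db[:n]
                rows.append(
                    dict(generation=gen, condition="hybrid-minus-human",
                         environment_type=etype, parameter=name,
                         estimate=a.result.point.estimate(name)
                         - b.result.point.estimate(name),
                         ci_low=float(np.percentile(diff, 2.5)),
                         ci_high=float(np.percentile(diff, 97.5)),
                         n_games=min(a.n_games, b.n_games), note="")
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta calibration


def calibrate_beta(
    target_mean_reward: float,
    envs: Sequence[Environment],
    gamma_g: float,
    gamma_s: float,
    beta_max: float = 1.0,
    tol: float = 0.5,
) -> float:
    """Inverse temperature matching a target mean performance.

    Root-finds ``beta`` such that the mean exact expected reward over
    ``envs`` (pruning rates fixed) equals ``target_mean_reward`` within
    ``tol`` points.  Raises ``ValueError`` when the target lies outside the
    achievable range, whose upper end is taken from a grid of increasing
    ``beta`` values up to ``beta_max``.
    """
    batch = stack_environments(list(envs))

    def mean_reward(beta: float) -> float:
        params = PruningParams(gamma_g, gamma_s, beta)
        return float(
            expected_reward_batch(batch.targets, batch.rewards, batch.start, params).mean()
        )

    f0 = mean_reward(0.0)
    grid = np.geomspace(1e-3, beta_max, 25)
    grid_vals = [mean_reward(b) for b in grid]
    f_max = max(f0, *grid_vals)
    if abs(target_mean_reward - f0) <= tol:
        return 0.0
    if target_mean_reward < min(f0, *grid_vals) - tol or target_mean_reward > f_max + tol:
        raise ValueError(
            f"target {target_mean_reward} outside achievable mean-reward range "
            f"[{min(f0, *grid_vals):.1f}, {f_max:.1f}]"
        )
    # bracket on the grid, then refine
    betas = np.concatenate([[0.0], grid])
    vals = np.array([f0] + grid_vals)
    above = np.flatnonzero(vals >= target_mean_reward)
    hi_i = int(above[0]) if above.size else len(betas) - 1
    lo_b = betas[max(hi_i - 1, 0)]
    hi_b = betas[hi_i]
    if lo_b == hi_b:
        return float(hi_b)
    beta = optimize.brentq(
        lambda b: mean_reward(b) - target_mean_reward, lo_b, hi_b, xtol=1e-8
    )
    achieved = mean_reward(beta)
    if abs(achieved - target_mean_reward) > tol:
        raise ValueError(
            f"calibration off target: reached {achieved:.2f} for target "
            f"{target_mean_reward:.2f}"
        )
    return float(beta)


# ---------------------------------------------------------------------------
# descriptive summary


@dataclass
class SummaryReport:
    """Descriptive tables of a simulated cohort."""

    per_generation: pd.DataFrame
    differences: pd.DataFrame
    matching: pd.DataFrame
    optimal_rates: pd.DataFrame

    def to_csv(self, out_dir) -> list[str]:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name in ("per_generation", "differences", "matching", "optimal_rates"):
            path = out / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            written.append(str(path))
        return written

    def plot(self, out_dir) -> list[str]:
        """Diagnostic plots (requires matplotlib)."""
        import pathlib

        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, etype in zip(axes, sorted(self.differences.environment_type.unique())):
            sub = self.differences[self.differences.environment_type == etype]
            ax.axhline(0.0, color="grey", lw=0.8)
            ax.errorbar(
                sub.generation,
                sub["mean"],
                yerr=[sub["mean"] - sub.ci_low, sub.ci_high - sub["mean"]],
                fmt="o-",
            )
            ax.set_title(etype)
            ax.set_xlabel("generation")
        axes[0].set_ylabel("hybrid - human-only reward")
        path = out / "reward_differences.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
        return written


def records_frame(records: Sequence[GameRecord]) -> pd.DataFrame:
    """Tidy frame of game records (one row per record)."""
    return pd.DataFrame(
        {
            "chain_id": r.chain_id,
            "environment_id": r.environment_id,
            "condition": r.condition,
            "environment_type": r.environment_type,
            "generation": r.generation,
            "player_type": r.player_type,
            "participant_id": r.participant_id,
            "solution": r.solution.path_str(),
            "total_reward": r.total_reward,
            "valid": r.valid,
            "n_large_costs": r.n_large_costs,
            "matches_prev": r.matches_prev,
            "matches_gen2": r.matches_gen2,
            "is_optimal": r.is_optimal,
            "copied": r.copied,
        }
        for r in records
    )


def summary_report(
    records: Sequence[GameRecord],
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> SummaryReport:
    """Per-generation descriptive statistics of a simulated cohort.

    ``differences`` holds the within-environment hybrid-minus-human reward
    difference per generation and environment type, with a percentile
    bootstrap CI over environments.
    """
    rng = np.random.default_rng(rng)
    df = records_frame([r for r in records if r.valid])
    if df.empty:
        raise ValueError("no valid records to summarize")
    keys = ["environment_type", "condition", "generation"]
    per_gen = (
        df.groupby(keys)["total_reward"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    per_gen["se"] = per_gen["sd"] / np.sqrt(per_gen["n"])

    wide = df.pivot_table(
        index=["environment_type", "environment_id", "generation"],
        columns="condition",
        values="total_reward",
    ).reset_index()
    rows = []
    if {"hybrid", "human-only"} <= set(wide.columns):
        wide["diff"] = wide["hybrid"] - wide["human-only"]
        for (etype, gen), sub in wide.groupby(["environment_type", "generation"]):
            d = sub["diff"].dropna().to_numpy()
            if d.size == 0:
                continue
            boots = rng.integers(0, d.size, size=(n_boot, d.size))
            means = d[boots].mean(axis=1)
            rows.append(
                dict(environment_type=etype, generation=gen, mean=float(d.mean()),
                     ci_low=float(np.percentile(means, 2.5)),
                     ci_high=float(np.percentile(means, 97.5)), n=int(d.size))
            )
    differences = pd.DataFrame(rows)

    matching = (
        df[df.matches_gen2 >= 0]
        .groupby(keys)["matches_gen2"]
        .agg(mean="mean", n="count")
        .reset_index()
    )
    optimal = df.groupby(keys)["is_optimal"].agg(rate="mean", n="count").reset_index()
    return SummaryReport(per_gen, differences, matching, optimal)
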