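"""Serialization, validation, manifests and run configuration.

Exchange formats are plain text: environment pools as JSON (one file per
pool with a manifest header), games tables as CSV with solutions serialized
as dash-separated node sequences (``"E-C-A-B-F-A-B-F-A"``).  Every writer
records a manifest (seed, config echo, stage counts, output checksums) so
seeded runs are reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .chains import GameRecord
from .core import (
    HORIZON,
    N_ACTIONS,
    N_NODES,
    NODE_LABELS,
    REWARD_VALUES,
    Environment,
    RewardNetwork,
    Solution,
    node_index,
)
from .envgen import EnvironmentPool

__all__ = [
    "RunConfig",
    "Manifest",
    "save_pool",
    "load_pool",
    "write_games",
    "read_games",
    "records_from_frame",
    "write_manifest",
    "file_checksum",
]

logger = logging.getLogger(__name__)

GAMES_COLUMNS = [
    "chain_id",
    "environment_id",
    "condition",
    "environment_type",
    "generation",
    "player_type",
    "participant_id",
    "solution",
    "total_reward",
    "valid",
    "n_large_costs",
    "matches_prev",
    "matches_gen2",
    "is_optimal",
    "copied",
]


@dataclass
class RunConfig:
    """Seed and per-stage parameters of a full pipeline run."""

    seed: int = 0
    n_networks: int = 60_000
    n_select_per_type: int = 400
    n_participants: int = 177
    max_rounds: int = 80
    n_boot: int = 100
    abm_chains: int = 12_500
    out_dir: str = "results"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Manifest:
    """Provenance record written next to every output artifact."""

    version: str = _pkg_version
    seed: int | None = None
    config: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(pathlib.Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(manifest: Manifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# environment pools (JSON)


def _env_to_obj(env: Environment) -> dict:
    edges = [
        {
            "source": NODE_LABELS[s],
            "target": NODE_LABELS[int(env.targets[s, a])],
            "reward": int(env.rewards[s, a]),
        }
        for s in range(N_NODES)
        for a in range(N_ACTIONS)
    ]
    return {
        "id": env.env_id,
        "nodes": list(NODE_LABELS),
        "edges": edges,
        "start": NODE_LABELS[env.start],
        "label": env.label,
        "optimal_reward": env.optimal_reward,
        "sensitivity": env.sensitivity,
    }


def _env_from_obj(obj: Mapping[str, Any]) -> Environment:
    for key in ("id", "nodes", "edges", "start", "label"):
        if key not in obj:
            raise ValueError(f"environment object missing field {key!r}")
    nodes = list(obj["nodes"])
    if sorted(nodes) != sorted(NODE_LABELS):
        raise ValueError(f"field 'nodes': expected the six nodes {NODE_LABELS}")
    targets = np.full((N_NODES, N_ACTIONS), -1, dtype=np.int64)
    rewards = np.zeros((N_NODES, N_ACTIONS), dtype=np.int64)
    seen: dict[int, int] = dict.fromkeys(range(N_NODES), 0)
    for edge in obj["edges"]:
        try:
            s = node_index(edge["source"])
            t = node_index(edge["target"])
            r = int(edge["reward"])
        except (KeyError, TypeError) as exc:
            raise ValueError(f"field 'edges': malformed edge {edge!r}") from exc
        if r not in REWARD_VALUES:
            raise ValueError(
                f"field 'edges': reward {r} not in the payoff set {REWARD_VALUES}"
            )
        a = seen[s]
        if a >= N_ACTIONS:
            raise ValueError(
                f"field 'edges': node {edge['source']} has more than "
                f"{N_ACTIONS} outgoing edges"
            )
        targets[s, a] = t
        rewards[s, a] = r
        seen[s] = a + 1
    short = [NODE_LABELS[s] for s, c in seen.items() if c < N_ACTIONS]
    if short:
        raise ValueError(f"field 'edges': nodes {short} have fewer than 2 out-edges")
    try:
        network = RewardNetwork(targets, rewards)
    except ValueError as exc:
        raise ValueError(f"field 'edges': {exc}") from exc
    opt = obj.get("optimal_reward")
    sens = obj.get("sensitivity")
    return Environment(
        network=network,
        start=node_index(obj["start"]),
        label=obj["label"],
        optimal_reward=None if opt is None else int(opt),
        sensitivity=None if sens is None else float(sens),
        env_id=str(obj["id"]),
    )


def save_pool(
    pool: EnvironmentPool | Sequence[Environment],
    path,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> None:
    """Write a pool (or plain environment list) as a JSON document."""
    if isinstance(pool, EnvironmentPool):
        envs, counts = pool.environments, pool.counts
        seed = seed if seed is not None else pool.seed
        config = config if config is not None else (pool.config or {})
    else:
        envs, counts = list(pool), {"environments": len(pool)}
    doc = {
        "manifest": dataclasses.asdict(
            Manifest(seed=seed, config=dict(config or {}), counts=dict(counts))
        ),
        "environments": [_env_to_obj(e) for e in envs],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_pool(path) -> EnvironmentPool:
    """Read and validate an environment-pool JSON document."""
    with open(path) as fh:
        doc = json.load(fh)
    if "environments" not in doc:
        raise ValueError("pool document missing field 'environments'")
    envs = [_env_from_obj(obj) for obj in doc["environments"]]
    man = doc.get("manifest", {})
    return EnvironmentPool(
        envs,
        counts=dict(man.get("counts", {})),
        seed=man.get("seed"),
        config=man.get("config"),
    )


# ---------------------------------------------------------------------------
# games tables (CSV)


def write_games(records: Sequence[GameRecord] | pd.DataFrame, path) -> None:
    """Write a games table CSV (one row per game record)."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        from .estimation import records_frame

        df = records_frame(records)
    missing = [c for c in GAMES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"games frame missing columns {missing}")
    df.to_csv(path, index=False, columns=GAMES_COLUMNS)


def read_games(
    path,
    pool: EnvironmentPool | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a games table CSV, validating rows.

    When ``pool`` is given, every solution string is re-validated as a walk
    through its environment; a hybrid chain without an algorithm row at
    generation 2 triggers a validation warning.  ``column_map`` renames
    foreign column names onto this package's schema (``{"their_name":
    "our_name"}``), allowing externally deposited tables to be ingested;
    columns of the schema that the foreign table lacks must still be
    supplied after renaming.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in GAMES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"games table missing columns {missing}")
    bad_gen = ~df.generation.between(1, HORIZON)
    if bad_gen.any():
        row = int(df.index[bad_gen][0])
        raise ValueError(
            f"row {row}: generation {df.generation.iloc[row]} outside 1..{HORIZON}"
        )
    if pool is not None:
        by_id = pool.by_id()
        for row, rec in enumerate(df.itertuples(index=False)):
            env = by_id.get(rec.environment_id)
            if env is None:
                raise ValueError(
                    f"row {row}: unknown environment {rec.environment_id!r}"
                )
            try:
                states = [node_index(tok) for tok in str(rec.solution).split("-")]
                Solution.from_states(env, states)
            except ValueError as exc:
                raise ValueError(f"row {row}: invalid solution string: {exc}") from exc
    valid = df[df.get("valid", True) == True]  # noqa: E712 - CSV booleans
    hybrid = valid[valid.condition == "hybrid"]
    for chain_id, sub in hybrid.groupby("chain_id"):
        gen2 = sub[sub.generation == 2]
        if gen2.empty or not (gen2.player_type == "algorithm").any():
            logger.warning(
                "hybrid chain %s has no algorithm record at generation 2", chain_id
            )
    return df


def records_from_frame(
    df: pd.DataFrame, pool: EnvironmentPool
) -> list[tuple[Environment, Solution]]:
    """(environment, solution) pairs for estimation, from a games frame."""
    by_id = pool.by_id()
    games = []
    for rec in df.itertuples(index=False):
        env = by_id[rec.environment_id]
        states = [node_index(tok) for tok in str(rec.solution).split("-")]
        games.append((env, Solution.from_states(env, states)))
    return games
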