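"""File formats: pellet CSV, performance CSV, trajectory CSV, YAML config.

Pellet sequences round-trip bit-exactly through CSV (floats are written
with shortest-round-trip repr).  Schemas are validated on read with
errors naming the offending column or trial.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arena import Arena
from .distributions import DistributionSequence, PelletDistribution
from .fitting import PerformanceSeries
from .metrics import Trajectory

__all__ = [
    "write_pellet_csv",
    "load_pellet_csv",
    "write_performance_csv",
    "load_performance_csv",
    "load_trajectory_csv",
    "load_events_csv",
    "load_config",
    "save_config",
]

PELLET_COLUMNS = ["trial", "session", "pellet_id", "x_cm", "y_cm"]


def write_pellet_csv(seq: DistributionSequence, path) -> None:
    rows = []
    for trial in seq.trials:
        s = seq.session_of(trial.trial_index)
        for pid, (x, y) in enumerate(trial.points):
            rows.append((trial.trial_index, s, pid, repr(float(x)), repr(float(y))))
    df = pd.DataFrame(rows, columns=PELLET_COLUMNS)
    df.to_csv(path, index=False)


def load_pellet_csv(
    path, arena: Arena | None = None, level: str = "unknown", seed: int | None = None
) -> DistributionSequence:
    """Read a pellet CSV back into a :class:`DistributionSequence`."""
    if arena is None:
        arena = Arena()
    df = pd.read_csv(path)
    missing = [c for c in PELLET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pellet CSV missing column(s): {', '.join(missing)}")
    if df.duplicated(subset=["trial", "pellet_id"]).any():
        raise ValueError("duplicate (trial, pellet_id) rows")
    df = df.sort_values(["session", "trial", "pellet_id"], kind="stable")
    trials = []
    for t, grp in df.groupby("trial", sort=True):
        pts = grp[["x_cm", "y_cm"]].to_numpy(dtype=float)
        dist = PelletDistribution(trial_index=int(t), points=pts)
        try:
            dist.validate(arena)
        except ValueError as e:
            raise ValueError(f"pellet CSV invalid: {e}") from e
        trials.append(dist)
    sizes = df.groupby("trial")["session"].first()
    per_session = int((sizes.groupby(sizes).size()).max()) if len(sizes) else 3
    seq = DistributionSequence(
        arena=arena,
        trials=trials,
        trials_per_session=per_session,
        level=level,
        seed=seed,
    )
    return seq


def write_performance_csv(series: PerformanceSeries, path) -> None:
    pd.DataFrame(
        {"trial": series.trials, "path_length_cm": series.lengths_cm}
    ).to_csv(path, index=False)


def load_performance_csv(path) -> PerformanceSeries:
    df = pd.read_csv(path)
    for col in ("trial", "path_length_cm"):
        if col not in df.columns:
            raise ValueError(f"performance CSV missing column: {col}")
    return PerformanceSeries(
        trials=df["trial"].to_numpy(), lengths_cm=df["path_length_cm"].to_numpy()
    )


def load_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path)
    for col in ("t_s", "x_cm", "y_cm"):
        if col not in df.columns:
            raise ValueError(f"trajectory CSV missing column: {col}")
    return Trajectory(
        times=df["t_s"].to_numpy(), positions=df[["x_cm", "y_cm"]].to_numpy()
    )


def load_events_csv(path) -> list[tuple[float, int]]:
    df = pd.read_csv(path)
    for col in ("t_s", "pellet_id"):
        if col not in df.columns:
            raise ValueError(f"events CSV missing column: {col}")
    return [(float(t), int(p)) for t, p in zip(df["t_s"], df["pellet_id"])]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def arena_from_config(cfg: dict) -> Arena:
    a = cfg.get("arena", {})
    kwargs = {}
    for key in ("length_cm", "width_cm", "n_cols", "n_rows"):
        if key in a:
            kwargs[key] = a[key]
    if "start" in a:
        kwargs["start"] = tuple(a["start"])
    return Arena(**kwargs)
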