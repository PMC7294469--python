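"""End-to-end synthetic experiment: generate -> solve -> simulate -> fit -> analyze.

Runs a three-cohort experiment (high/medium/low predictability, n
subjects each) from a single config, writing per-stage CSV/JSON artifacts
plus a manifest recording seeds, stage artifacts and the package version.
All randomness flows from one root seed split per stage/subject with
``numpy.random.SeedSequence``, so a rerun with the same config is
bit-identical (excluding the manifest timestamp).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .distributions import (
    DistributionSequence,
    LEVELS,
    across_trial_min_distance,
    generate_sequence,
    re_trajectory,
)
from .fitting import (
    COARSE_GRID,
    fit_parameters,
    memory_usage,
    performance_series,
    sensory_acuity,
)
from .io import write_pellet_csv, write_performance_csv
from .routes import nearest_neighbor_route, optimal_route
from .studies import COHORT_PARAMS, COHORT_RE_WIDTH_CM, COHORT_SEQUENCE_KW

__all__ = ["DEFAULT_CONFIG", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_subjects": 2,
    "n_sessions": 8,
    "trials_per_session": 3,
    "start_trial": 13,
    "snap_to_grid": True,
    "levels": list(LEVELS),
    "grid": "coarse",
}


def _stage_seed(root: int, stage: str, index: int = 0) -> int:
    ss = np.random.SeedSequence([root, zlib.crc32(stage.encode()), index])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: dict | None = None, out_dir=None) -> Path:
    """Execute all stages; returns the run directory containing the manifest."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    out = Path(out_dir) if out_dir is not None else Path("pipeline_run")
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    root = int(cfg["seed"])
    stage = "init"
    try:
        # -- stage 1: generate ------------------------------------------------
        stage = "generate"
        sequences: dict[tuple[str, int], DistributionSequence] = {}
        for li, level in enumerate(cfg["levels"]):
            for s in range(cfg["n_subjects"]):
                seq = generate_sequence(
                    level,
                    n_sessions=cfg["n_sessions"],
                    trials_per_session=cfg["trials_per_session"],
                    seed=_stage_seed(root, "generate", 100 * li + s),
                    snap_to_grid=cfg["snap_to_grid"],
                    **COHORT_SEQUENCE_KW.get(level, {}),
                )
                sequences[(level, s)] = seq
                p = out / f"pellets_{level}_{s}.csv"
                write_pellet_csv(seq, p)
                artifacts.append(p.name)

        # -- stage 2: solve ---------------------------------------------------
        stage = "solve"
        rows = []
        for (level, s), seq in sequences.items():
            for trial in seq.trials:
                opt = optimal_route(seq.arena.start, trial)
                nn = nearest_neighbor_route(seq.arena.start, trial)
                rows.append((level, s, trial.trial_index, opt.length_cm, nn.length_cm))
        routes = pd.DataFrame(
            rows, columns=["level", "subject", "trial", "optimal_cm", "nn_cm"]
        )
        routes.to_csv(out / "routes.csv", index=False)
        artifacts.append("routes.csv")

        # -- stage 3: simulate synthetic subjects -----------------------------
        stage = "simulate"
        targets = {}
        for (level, s), seq in sequences.items():
            series = performance_series(seq, COHORT_PARAMS[level], cfg["start_trial"])
            targets[(level, s)] = series
            p = out / f"performance_{level}_{s}.csv"
            write_performance_csv(series, p)
            artifacts.append(p.name)

        # -- stage 4: fit -----------------------------------------------------
        stage = "fit"
        grid = COARSE_GRID if cfg["grid"] == "coarse" else None
        fits = {}
        for (level, s), seq in sequences.items():
            fit = fit_parameters(targets[(level, s)], seq, grid_spec=grid)
            fits[(level, s)] = fit
        fit_out = {
            f"{level}_{s}": {
                "best_params": asdict(fit.best_params) if fit.best_params else None,
                "best_r": None if np.isnan(fit.best_r) else fit.best_r,
                "pr_by_md": {
                    ("cum" if md is None else str(md)): (None if np.isnan(v) else v)
                    for md, v in fit.pr_by_md.items()
                },
            }
            for (level, s), fit in fits.items()
        }
        (out / "fits.json").write_text(json.dumps(fit_out, indent=2))
        artifacts.append("fits.json")

        # -- stage 5: analyze -------------------------------------------------
        stage = "analyze"
        se_set = [
            f.best_params.se for f in fits.values() if f.best_params is not None
        ]
        rows = []
        for (level, s), seq in sequences.items():
            fit = fits[(level, s)]
            re_mean = float(np.mean(re_trajectory(seq, width_cm=COHORT_RE_WIDTH_CM)))
            shift = float(
                np.mean(
                    [
                        np.mean(across_trial_min_distance(b, a))
                        for a, b in zip(seq.trials[:-1], seq.trials[1:])
                    ]
                )
            )
            sa = mi = np.nan
            if fit.best_params is not None:
                sa = sensory_acuity(fit.best_params.se, se_set, fit.best_params.sw)
                mi = memory_usage(fit.pr_by_md)
            rows.append((level, s, re_mean, shift, sa, mi, fit.best_r))
        pd.DataFrame(
            rows,
            columns=["level", "subject", "re_bits", "min_shift_cm", "sa", "mi", "best_r"],
        ).to_csv(out / "metrics.csv", index=False)
        artifacts.append("metrics.csv")

        # -- stage 6: manifest ------------------------------------------------
        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": cfg,
            "root_seed": root,
            "artifacts": sorted(artifacts),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as e:  # preserve partial outputs, name the stage
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e
    return out
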