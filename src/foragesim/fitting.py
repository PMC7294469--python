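"""Grid fitting of agent parameters to trial-by-trial performance.

Goodness of fit is the Pearson correlation between the per-trial path
lengths of a simulated searcher and a target series (an animal, or a
synthetic subject).  The fit scans a coarse 3-D grid over the sensory
weight ``sw``, sensory decay ``se`` and memory depth ``md``; the derived
indices condense the best fit into a sensory-acuity score ``sa`` and a
long-term-memory-usage score ``mi``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .agent import AgentParams, _run_trial_core, occupancy_map
from .arena import Arena
from .distributions import DistributionSequence

__all__ = [
    "PerformanceSeries",
    "FitResult",
    "DEFAULT_GRID",
    "COARSE_GRID",
    "performance_series",
    "fit_parameters",
    "sensory_acuity",
    "memory_usage",
    "shuffled_prior_ratio",
    "cumulative_vs_single_memory",
]

#: Full fitting grid (the coarse 3-D grid of the search model).
DEFAULT_GRID: dict[str, tuple] = {
    "sw": tuple(np.round(np.arange(0.0, 1.01, 0.1), 1)),
    "se": (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0),
    "md": (1, 2, 3, 5, 10, None),
}

#: Reduced grid for simulation studies (parameter recovery, cohort fits).
COARSE_GRID: dict[str, tuple] = {
    "sw": (0.0, 0.25, 0.5, 0.75, 1.0),
    "se": (0.5, 2.0, 8.0, 32.0),
    "md": (1, 2, None),
}


@dataclass
class PerformanceSeries:
    """Per-trial path lengths (cm) for a subject or simulated agent."""

    trials: np.ndarray
    lengths_cm: np.ndarray

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=int)
        self.lengths_cm = np.asarray(self.lengths_cm, dtype=float)
        if self.trials.shape != self.lengths_cm.shape:
            raise ValueError("trials and lengths must align")
        if np.any(self.lengths_cm <= 0):
            raise ValueError("path lengths must be positive")


@dataclass
class FitResult:
    """Best-fit parameters, the full correlation grid, and pr as a function
    of memory depth at the best (sw, se)."""

    best_params: AgentParams | None
    best_r: float
    grid: dict[tuple, float]
    pr_by_md: dict[object, float]


# ---------------------------------------------------------------------------
# simulation of performance series
# ---------------------------------------------------------------------------

def _occupancy_cumsum(seq: DistributionSequence) -> np.ndarray:
    """(T+1, n_cells) cumulative per-trial occupancy, for O(1) prior windows."""
    occ = np.stack([occupancy_map(tr, seq.arena).ravel() for tr in seq.trials])
    zero = np.zeros((1, occ.shape[1]))
    return np.concatenate([zero, np.cumsum(occ, axis=0)])


def _pe_window(csum: np.ndarray, t: int, md: int | None) -> np.ndarray:
    L = 1 if md is None else max(t - md, 1)
    return (csum[t - 1] - csum[L - 1]) / (t - L)


def performance_series(
    seq: DistributionSequence,
    params: AgentParams,
    start_trial: int,
    arena: Arena | None = None,
    prior_csum: np.ndarray | None = None,
    step_cap: int | None = None,
) -> PerformanceSeries:
    """Run the agent on every trial from ``start_trial`` on, each time with
    the history of all preceding trials, and collect path lengths."""
    if arena is None:
        arena = seq.arena
    if start_trial < 2 or seq.n_trials - start_trial + 1 < 2:
        raise ValueError("start_trial must leave at least 2 trials with history")
    if prior_csum is None:
        prior_csum = _occupancy_cumsum(seq)
    trials = np.arange(start_trial, seq.n_trials + 1)
    lengths = np.empty(len(trials))
    for i, t in enumerate(trials):
        pe = _pe_window(prior_csum, t, params.md)
        res = _run_trial_core(
            seq.trials[t - 1], pe, params, arena, step_cap=step_cap, record_path=False
        )
        lengths[i] = res.path_length_cm
    return PerformanceSeries(trials=trials, lengths_cm=lengths)


# ---------------------------------------------------------------------------
# grid fit
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.corrcoef(a, b)[0, 1])


def _md_sort_key(md) -> float:
    return np.inf if md is None else float(md)


def fit_parameters(
    target: PerformanceSeries,
    seq: DistributionSequence,
    grid_spec: dict[str, tuple] | None = None,
    start_trial: int | None = None,
) -> FitResult:
    """Exhaustive correlation scan over the (sw, se, md) grid.

    Grid points whose simulated series has zero variance score as missing
    (undefined correlation) and can never be the best fit unless every
    point is undefined.  Exact correlation ties break toward smaller sw,
    then smaller se, then smaller md (cumulative last).  Combinations that
    are behaviorally degenerate (se is inert at sw = 0, md at sw = 1) are
    simulated once and shared.
    """
    if grid_spec is None:
        grid_spec = DEFAULT_GRID
    if start_trial is None:
        start_trial = int(target.trials[0])
    if int(target.trials[0]) != start_trial or len(target.trials) != (
        seq.n_trials - start_trial + 1
    ):
        raise ValueError("target series does not align with the sequence trials")

    csum = _occupancy_cumsum(seq)
    cache: dict[tuple, np.ndarray] = {}
    grid: dict[tuple, float] = {}
    for sw, se, md in itertools.product(
        grid_spec["sw"], grid_spec["se"], grid_spec["md"]
    ):
        key = (sw, se if sw > 0 else None, md if sw < 1 else None)
        if key not in cache:
            series = performance_series(
                seq, AgentParams(sw=sw, se=se, md=md), start_trial, prior_csum=csum
            )
            cache[key] = series.lengths_cm
        grid[(sw, se, md)] = _pearson(target.lengths_cm, cache[key])

    finite = {k: v for k, v in grid.items() if np.isfinite(v)}
    if not finite:
        return FitResult(best_params=None, best_r=np.nan, grid=grid, pr_by_md={})
    best_key = min(
        finite, key=lambda k: (-finite[k], k[0], k[1], _md_sort_key(k[2]))
    )
    sw_b, se_b, md_b = best_key
    pr_by_md = {md: grid[(sw_b, se_b, md)] for md in grid_spec["md"]}
    return FitResult(
        best_params=AgentParams(sw=sw_b, se=se_b, md=md_b),
        best_r=finite[best_key],
        grid=grid,
        pr_by_md=pr_by_md,
    )


# ---------------------------------------------------------------------------
# derived indices
# ---------------------------------------------------------------------------

def sensory_acuity(se_best: float, se_set, sw_best: float) -> float:
    """sa = (1 - se_best / max(se_set) + sw_best) / 2.

    ``se_set`` is the set of best-fit sensory exponents across the cohort;
    normalizing by its maximum keeps sa in [0, 1].  Larger sa means higher
    sensory weight and/or longer sensing range.
    """
    se_set = np.asarray(list(se_set), dtype=float)
    if se_set.size == 0 or se_set.max() <= 0:
        raise ValueError("se_set must be non-empty with a positive maximum")
    return (1.0 - se_best / se_set.max() + sw_best) / 2.0


def memory_usage(pr_by_md: dict[object, float]) -> float:
    """mi = (max(pr) - mean(pr at md < 3)) / (max(pr) - min(pr)).

    Normalized gain of long over short memory: near 1 when only long or
    cumulative memory tracks the target, 0 for a flat profile (defined as
    0 when max(pr) == min(pr)).
    """
    vals = np.array([v for v in pr_by_md.values()], dtype=float)
    vals = vals[np.isfinite(vals)]
    short = [
        v
        for md, v in pr_by_md.items()
        if md is not None and md < 3 and np.isfinite(v)
    ]
    if vals.size == 0 or not short:
        raise ValueError("pr_by_md must contain finite values incl. md in {1, 2}")
    hi, lo = vals.max(), vals.min()
    if hi == lo:
        return 0.0
    return float((hi - np.mean(short)) / (hi - lo))


def shuffled_prior_ratio(
    seq: DistributionSequence,
    donor_seq: DistributionSequence,
    params: AgentParams,
    start_trial: int,
) -> float:
    """Mean path length with the donor sequence's history as prior, over the
    mean path length with the sequence's own history.

    A ratio near 1 means the prior carries no usable information (as for
    actively randomized placements); ratios above 1 quantify the cost of a
    wrong prior on predictable placements.
    """
    if donor_seq.n_trials < seq.n_trials:
        raise ValueError("donor sequence must cover the same trials")
    own = performance_series(seq, params, start_trial)
    donor_csum = _occupancy_cumsum(donor_seq)
    swapped = performance_series(seq, params, start_trial, prior_csum=donor_csum)
    return float(swapped.lengths_cm.mean() / own.lengths_cm.mean())


def cumulative_vs_single_memory(
    seq: DistributionSequence,
    target: PerformanceSeries,
    sw: float,
    se: float,
    start_trial: int | None = None,
) -> tuple[float, float]:
    """Correlations with the target at md = 1 and md = cumulative, holding
    (sw, se) fixed; returns (r_md1, r_cum)."""
    if start_trial is None:
        start_trial = int(target.trials[0])
    csum = _occupancy_cumsum(seq)
    rs = []
    for md in (1, None):
        series = performance_series(
            seq, AgentParams(sw=sw, se=se, md=md), start_trial, prior_csum=csum
        )
        rs.append(_pearson(target.lengths_cm, series.lengths_cm))
    return rs[0], rs[1]
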