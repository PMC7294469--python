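"""Fixed-start open traveling-salesman routing layer.

A trial's pellets define an open TSP instance: the route starts at the
arena entrance, visits every pellet exactly once, and does not return.
Three solvers are provided —

* :func:`brute_force_route` — exhaustive oracle for small instances,
* :func:`ga_route` — a genetic algorithm (groups-of-four selection with
  flip/swap/slide mutations, elite carryover),
* :func:`nearest_neighbor_route` — the greedy heuristic animals appear
  to approximate,

plus the efficiency metrics built on their path lengths.  All tie-breaks
are deterministic (lowest pellet index / lexicographic order) so results
are exactly reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionSequence",
    "GAConfig",
    "path_length",
    "brute_force_route",
    "ga_route",
    "nearest_neighbor_route",
    "optimal_route",
    "foraging_efficiency",
    "count_sequences",
    "nn_vs_optimal_gap",
]

_BRUTE_FORCE_MAX = 10


@dataclass(frozen=True)
class AcquisitionSequence:
    """A pellet visiting order and the length of the open path realizing it."""

    order: tuple[int, ...]
    length_cm: float


@dataclass
class GAConfig:
    """Genetic-algorithm settings.

    Each generation the population is shuffled into groups of four; the
    shortest member of each group survives and seeds three mutants (segment
    flip, endpoint swap, slide).  The top ``elite_fraction`` of the previous
    generation is carried over unchanged, so the best length is monotone
    non-increasing.  The run stops at ``n_generations``, when the best
    length is within ``early_stop_tol`` of the instance lower bound, or
    after ``stall_generations`` generations without improvement.
    """

    population_size: int = 80
    n_generations: int = 2000
    elite_fraction: float = 0.05
    seed: int = 0
    early_stop_tol: float = 1e-6
    stall_generations: int = 500

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be at least 4")
        if self.n_generations < 1:
            raise ValueError("n_generations must be at least 1")


def _as_points(pellets) -> np.ndarray:
    """Accept a PelletDistribution or a raw (n, 2) array."""
    pts = getattr(pellets, "points", pellets)
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("pellets must be a non-empty (n, 2) coordinate array")
    return pts


def path_length(start, points: np.ndarray, order) -> float:
    """Length of the open path start -> points[order[0]] -> ... -> points[order[-1]]."""
    pts = np.asarray(points, dtype=float)[list(order)]
    full = np.vstack([np.asarray(start, dtype=float), pts])
    return float(np.linalg.norm(np.diff(full, axis=0), axis=1).sum())


def _lengths_of_orders(start: np.ndarray, pts: np.ndarray, orders: np.ndarray) -> np.ndarray:
    """Vectorized path lengths for a (k, n) array of permutations."""
    routed = pts[orders]  # (k, n, 2)
    first = np.linalg.norm(routed[:, 0, :] - start, axis=1)
    segs = np.linalg.norm(np.diff(routed, axis=1), axis=2).sum(axis=1)
    return first + segs


def brute_force_route(start, pellets) -> AcquisitionSequence:
    """Globally shortest open route by exhaustive enumeration (<= 10 pellets).

    Ties are broken lexicographically on the visiting order, so the result
    is unique and deterministic.
    """
    pts = _as_points(pellets)
    n = len(pts)
    if n > _BRUTE_FORCE_MAX:
        raise ValueError(f"brute force limited to {_BRUTE_FORCE_MAX} pellets, got {n}")
    start = np.asarray(start, dtype=float)
    best_len = np.inf
    best_order: tuple[int, ...] | None = None
    chunk = 40320  # enumerate lexicographically in bounded chunks
    it = itertools.permutations(range(n))
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        orders = np.array(block, dtype=np.intp)
        lengths = _lengths_of_orders(start, pts, orders)
        i = int(np.argmin(lengths))  # first minimum = lexicographically smallest
        if lengths[i] < best_len:
            best_len = float(lengths[i])
            best_order = tuple(int(j) for j in orders[i])
    assert best_order is not None
    return AcquisitionSequence(order=best_order, length_cm=best_len)


def _segment_indices(rng: np.random.Generator, n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k random (i, j) index pairs with i <= j, for mutation segments."""
    a = rng.integers(0, n, size=k)
    b = rng.integers(0, n, size=k)
    return np.minimum(a, b), np.maximum(a, b)


def ga_route(start, pellets, cfg: GAConfig | None = None) -> AcquisitionSequence:
    """Genetic-algorithm solution of the fixed-start open TSP.

    Deterministic given ``cfg.seed``; the returned route is never longer
    than the best member of the initial random population.
    """
    if cfg is None:
        cfg = GAConfig()
    pts = _as_points(pellets)
    n = len(pts)
    start = np.asarray(start, dtype=float)
    if n == 1:
        return AcquisitionSequence(order=(0,), length_cm=path_length(start, pts, [0]))

    rng = np.random.default_rng(cfg.seed)
    pop_size = max(4, (cfg.population_size // 4) * 4)
    pop = np.array([rng.permutation(n) for _ in range(pop_size)], dtype=np.intp)
    n_elite = max(1, int(round(cfg.elite_fraction * pop_size)))
    # a route must at least reach the farthest pellet from the start
    lower_bound = float(np.linalg.norm(pts - start, axis=1).max())

    lengths = _lengths_of_orders(start, pts, pop)
    best_i = int(np.argmin(lengths))
    best_len = float(lengths[best_i])
    best_order = pop[best_i].copy()
    stall = 0

    cols = np.arange(n)
    for _ in range(cfg.n_generations):
        if best_len <= lower_bound + cfg.early_stop_tol or stall >= cfg.stall_generations:
            break
        elite = pop[np.argsort(lengths, kind="stable")[:n_elite]].copy()
        groups = rng.permutation(pop_size).reshape(-1, 4)
        g = groups.shape[0]
        group_lengths = lengths[groups]
        winners = pop[groups[np.arange(g), np.argmin(group_lengths, axis=1)]]  # (g, n)

        i, j = _segment_indices(rng, n, g)
        i, j = i[:, None], j[:, None]
        base = np.broadcast_to(cols, (g, n))
        inseg = (base >= i) & (base <= j)
        flip_idx = np.where(inseg, i + j - base, base)
        swap_idx = base.copy()
        rows = np.arange(g)
        swap_idx[rows, i[:, 0]] = j[:, 0]
        swap_idx[rows, j[:, 0]] = i[:, 0]
        slide_idx = np.where(inseg, np.where(base < j, base + 1, i), base)

        children = np.stack(
            [
                winners,
                np.take_along_axis(winners, flip_idx, axis=1),
                np.take_along_axis(winners, swap_idx, axis=1),
                np.take_along_axis(winners, slide_idx, axis=1),
            ],
            axis=1,
        ).reshape(pop_size, n)
        children[:n_elite] = elite
        pop = children
        lengths = _lengths_of_orders(start, pts, pop)
        gen_best = int(np.argmin(lengths))
        if lengths[gen_best] < best_len - 1e-12:
            best_len = float(lengths[gen_best])
            best_order = pop[gen_best].copy()
            stall = 0
        else:
            stall += 1

    return AcquisitionSequence(
        order=tuple(int(k) for k in best_order), length_cm=best_len
    )


def nearest_neighbor_route(start, pellets) -> AcquisitionSequence:
    """Greedy route: always travel to the nearest unvisited pellet.

    Exact distance ties are broken toward the lowest pellet index.
    """
    pts = _as_points(pellets)
    n = len(pts)
    pos = np.asarray(start, dtype=float)
    remaining = list(range(n))
    order: list[int] = []
    total = 0.0
    while remaining:
        d = np.linalg.norm(pts[remaining] - pos, axis=1)
        k = int(np.argmin(d))  # first minimum = lowest index among ties
        total += float(d[k])
        pos = pts[remaining[k]]
        order.append(remaining.pop(k))
    return AcquisitionSequence(order=tuple(order), length_cm=total)


def optimal_route(start, pellets, exact_max: int = 8, ga_cfg: GAConfig | None = None) -> AcquisitionSequence:
    """Optimal (or near-optimal) route: exhaustive up to ``exact_max`` pellets, GA beyond."""
    pts = _as_points(pellets)
    if len(pts) <= exact_max:
        return brute_force_route(start, pts)
    if ga_cfg is None:
        ga_cfg = GAConfig(population_size=64, n_generations=600, stall_generations=150, seed=0)
    return ga_route(start, pts, ga_cfg)


def foraging_efficiency(lo: float, la: float) -> float:
    """Foraging efficiency fe = lo / la (optimal over actual path length)."""
    if lo <= 0 or la <= 0:
        raise ValueError("path lengths must be positive")
    return lo / la


def count_sequences(n_pellets: int) -> int:
    """Number of possible acquisition sequences for n pellets: n!."""
    if n_pellets < 0:
        raise ValueError("pellet count must be non-negative")
    return math.factorial(n_pellets)


def nn_vs_optimal_gap(start, pellets) -> float:
    """Fractional excess of the nearest-neighbor route over the optimal route."""
    opt = brute_force_route(start, pellets)
    nn = nearest_neighbor_route(start, pellets)
    return (nn.length_cm - opt.length_cm) / opt.length_cm
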