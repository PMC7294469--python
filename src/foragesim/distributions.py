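"""Synthetic pellet placements with controlled predictability.

Each trial baits the arena with pellets organized into a few clusters
(three clusters of roughly three pellets in the behavioral task, about
seven pellets per trial on average).  Sequences of trials come in three
predictability levels:

* ``high``   — one placement repeated identically on every trial,
* ``medium`` — cluster centers drift as a Gaussian random walk between
  sessions (placements within a session are identical),
* ``low``    — a fresh placement every trial, accepted only if every
  pellet is at least ``min_shift_cm`` from all pellets of the previous
  trial.

All accepted placements are additionally constrained to have (near-)
equal optimal open-TSP path lengths, so route difficulty is matched
across levels.  Predictability is quantified by the across-trial minimum
distance metric and by the relative entropy (KL divergence, in bits) of
each trial's smoothed pellet density against the density pooled over all
previous trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.spatial.distance import cdist
from scipy.special import rel_entr

from .arena import Arena, ScalarField
from .routes import AcquisitionSequence, optimal_route

__all__ = [
    "PelletDistribution",
    "DistributionSequence",
    "make_cluster_trial",
    "generate_sequence",
    "across_trial_min_distance",
    "smooth_density",
    "relative_entropy",
    "re_trajectory",
    "constrain_optimal_length",
    "LEVELS",
    "DEFAULT_TARGET_LEN_CM",
]

LEVELS = ("high", "medium", "low")

#: Target optimal open-path length (cm) used to match route difficulty across
#: levels; chosen once in the typical range of 3-cluster placements in the
#: 250 x 100 cm arena.
DEFAULT_TARGET_LEN_CM = 250.0

#: Pseudocount floor applied to smoothed densities so relative entropy is
#: defined everywhere.
DENSITY_FLOOR = 1e-9


@dataclass(frozen=True)
class PelletDistribution:
    """One trial's pellet coordinates (continuous arena centimeters)."""

    trial_index: int
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
            raise ValueError("points must be a non-empty (n, 2) array")
        object.__setattr__(self, "points", pts)

    @property
    def n_pellets(self) -> int:
        return len(self.points)

    def validate(self, arena: Arena) -> None:
        pts = self.points
        if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > arena.length_cm) or np.any(
            pts[:, 1] < 0
        ) or np.any(pts[:, 1] > arena.width_cm):
            raise ValueError(f"trial {self.trial_index}: pellet outside arena bounds")
        if len(pts) > 1:
            cells = arena.points_to_flat_cells(pts)
            if len(np.unique(cells)) < len(cells):
                raise ValueError(
                    f"trial {self.trial_index}: duplicate pellets within one grid cell"
                )


@dataclass
class DistributionSequence:
    """Ordered trials of pellet placements sharing one arena.

    ``trials`` are indexed 1..T consecutively and grouped into sessions of
    ``trials_per_session`` (three per day in the behavioral task).
    """

    arena: Arena
    trials: list[PelletDistribution]
    trials_per_session: int = 3
    level: str = "unknown"
    seed: int | None = None

    def __post_init__(self) -> None:
        got = [t.trial_index for t in self.trials]
        if got != list(range(1, len(self.trials) + 1)):
            raise ValueError("trial_index values must be consecutive from 1")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_sessions(self) -> int:
        return -(-len(self.trials) // self.trials_per_session)

    def session_of(self, trial_index: int) -> int:
        return 1 + (trial_index - 1) // self.trials_per_session

    @property
    def sessions(self) -> list[list[PelletDistribution]]:
        k = self.trials_per_session
        return [self.trials[i : i + k] for i in range(0, len(self.trials), k)]

    def validate(self) -> None:
        for t in self.trials:
            t.validate(self.arena)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _scatter_clusters(
    rng: np.random.Generator,
    arena: Arena,
    centers: np.ndarray,
    sizes: Sequence[int],
    cluster_sd_cm: float,
    margin_cm: float,
) -> np.ndarray:
    pts = []
    for c, k in zip(centers, sizes):
        offs = rng.normal(0.0, cluster_sd_cm, size=(k, 2)) if cluster_sd_cm > 0 else np.zeros((k, 2))
        pts.append(c + offs)
    pts = np.vstack(pts)
    pts[:, 0] = np.clip(pts[:, 0], 0.0, arena.length_cm)
    pts[:, 1] = np.clip(pts[:, 1], 0.0, arena.width_cm)
    return pts


def _min_pairwise(pts: np.ndarray) -> float:
    if len(pts) < 2:
        return np.inf
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    return float(d.min())


def _draw_sizes(
    rng: np.random.Generator,
    n_clusters: int,
    lo: int,
    hi: int,
    preset: str | None,
) -> np.ndarray:
    if preset == "paper_mean7":
        # a random ordering of (2, 2, 3)-style sizes targeting 7 pellets/trial
        base = np.full(n_clusters, 2, dtype=int)
        base[: max(0, 7 - 2 * n_clusters)] += 1
        return rng.permutation(base)
    return rng.integers(lo, hi + 1, size=n_clusters)


def make_cluster_trial(
    arena: Arena,
    rng_seed: int | np.random.Generator,
    n_clusters: int = 3,
    pellets_per_cluster_range: tuple[int, int] = (2, 3),
    cluster_sd_cm: float = 12.0,
    margin_cm: float = 20.0,
    trial_index: int = 1,
    preset: str | None = None,
    max_attempts: int = 200,
) -> PelletDistribution:
    """Draw one trial: Gaussian pellet scatter around uniform cluster centers.

    Cluster centers are uniform within the margin-inset arena; each cluster
    contributes a uniform draw from ``pellets_per_cluster_range`` pellets
    (``preset='paper_mean7'`` instead permutes sizes summing to 7).  A draw
    is rejected and resampled if any two pellets fall within one grid-cell
    diagonal of each other; persistent failure signals an infeasible
    margin/sd combination.
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    if cluster_sd_cm < 0:
        raise ValueError("cluster sd must be non-negative")
    lo, hi = pellets_per_cluster_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid pellets_per_cluster_range")
    if margin_cm < 0 or 2 * margin_cm >= min(arena.length_cm, arena.width_cm):
        raise ValueError("margin leaves no room for clusters")
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_attempts):
        centers = np.column_stack(
            [
                rng.uniform(margin_cm, arena.length_cm - margin_cm, size=n_clusters),
                rng.uniform(margin_cm, arena.width_cm - margin_cm, size=n_clusters),
            ]
        )
        sizes = _draw_sizes(rng, n_clusters, lo, hi, preset)
        pts = _scatter_clusters(rng, arena, centers, sizes, cluster_sd_cm, margin_cm)
        if len(pts) == 1 or _min_pairwise(pts) >= arena.cell_diag:
            dist = PelletDistribution(trial_index=trial_index, points=pts)
            dist.validate(arena)
            return dist
    raise RuntimeError(
        f"could not place {n_clusters} clusters after {max_attempts} attempts "
        "(margin/sd infeasible)"
    )


def _cluster_trial_with_centers(
    arena: Arena,
    centers: np.ndarray,
    offsets: list[np.ndarray],
    trial_index: int,
) -> PelletDistribution | None:
    pts = np.vstack([c + off for c, off in zip(centers, offsets)])
    pts[:, 0] = np.clip(pts[:, 0], 0.0, arena.length_cm)
    pts[:, 1] = np.clip(pts[:, 1], 0.0, arena.width_cm)
    if len(pts) > 1 and _min_pairwise(pts) < arena.cell_diag:
        return None
    return PelletDistribution(trial_index=trial_index, points=pts)


def generate_sequence(
    level: str,
    n_sessions: int = 20,
    trials_per_session: int = 3,
    seed: int = 0,
    drift_sd_cm: float = 5.0,
    min_shift_cm: float = 20.0,
    arena: Arena | None = None,
    target_len_cm: float = DEFAULT_TARGET_LEN_CM,
    tol_frac: float = 0.15,
    cluster_sd_cm: float = 12.0,
    n_clusters: int = 3,
    pellets_per_cluster_range: tuple[int, int] = (2, 3),
    preset: str | None = None,
    snap_to_grid: bool = False,
    resample_scatter: bool = False,
    max_attempts: int = 400,
    solver: Callable | None = None,
) -> DistributionSequence:
    """Generate a pellet-placement sequence at a given predictability level.

    Every accepted placement passes :func:`constrain_optimal_length`, so the
    three levels present routes of matched optimal length.  With
    ``snap_to_grid`` pellets are projected onto occupancy-grid cell centers
    (the representation the search agent operates on) and ordered row-major.

    By default ``high`` repeats one placement identically and ``medium``
    re-places pellets only when its cluster centers drift between sessions.
    With ``resample_scatter`` the pellet scatter (and per-cluster pellet
    count) is redrawn around the cluster centers on every trial instead,
    emulating a dispenser realizing a *stationary distribution* trial by
    trial: locations stay predictable at the cluster level while exact
    coordinates and pellet counts vary.  Fully deterministic given ``seed``
    and the parameters.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if n_sessions < 1 or trials_per_session < 1:
        raise ValueError("need at least one session of at least one trial")
    if arena is None:
        arena = Arena()
    rng = np.random.default_rng(seed)
    n_trials = n_sessions * trials_per_session

    def finalize(pts: np.ndarray, idx: int) -> PelletDistribution:
        if snap_to_grid:
            pts = arena.snap_to_grid(pts)
            pts = pts[np.argsort(arena.points_to_flat_cells(pts), kind="stable")]
        return PelletDistribution(trial_index=idx, points=pts)

    def accepted(dist: PelletDistribution) -> bool:
        return constrain_optimal_length(
            dist, target_len_cm, tol_frac, solver=solver, start=arena.start
        )

    def draw_offsets(sizes) -> list[np.ndarray]:
        return [
            rng.normal(0.0, cluster_sd_cm, size=(k, 2))
            if cluster_sd_cm > 0
            else np.zeros((k, 2))
            for k in sizes
        ]

    trials: list[PelletDistribution] = []

    if level in ("high", "medium"):
        # base layout: cluster centers plus per-pellet offsets, so the whole
        # placement can translate with its (possibly drifting) centers
        for _ in range(max_attempts):
            centers = np.column_stack(
                [
                    rng.uniform(20.0, arena.length_cm - 20.0, size=n_clusters),
                    rng.uniform(20.0, arena.width_cm - 20.0, size=n_clusters),
                ]
            )
            sizes = _draw_sizes(rng, n_clusters, *pellets_per_cluster_range, preset)
            cand = _cluster_trial_with_centers(arena, centers, draw_offsets(sizes), 1)
            if cand is not None and accepted(cand):
                break
        else:
            raise RuntimeError("no base placement met the optimal-length constraint")
        session_pts = cand.points
        t = 0
        for s in range(1, n_sessions + 1):
            if s > 1 and level == "medium":
                for _ in range(max_attempts):
                    step = rng.normal(0.0, drift_sd_cm, size=centers.shape)
                    new_centers = np.clip(
                        centers + step,
                        [15.0, 15.0],
                        [arena.length_cm - 15.0, arena.width_cm - 15.0],
                    )
                    cand = _cluster_trial_with_centers(
                        arena, new_centers, draw_offsets(sizes), 1
                    )
                    if cand is not None and accepted(cand):
                        centers = new_centers
                        session_pts = cand.points
                        break
                else:
                    raise RuntimeError("drift step never met the optimal-length constraint")
            for _ in range(trials_per_session):
                t += 1
                if resample_scatter:
                    for _ in range(max_attempts):
                        new_sizes = _draw_sizes(
                            rng, n_clusters, *pellets_per_cluster_range, preset
                        )
                        cand = _cluster_trial_with_centers(
                            arena, centers, draw_offsets(new_sizes), t
                        )
                        if cand is not None and accepted(cand):
                            session_pts = cand.points
                            break
                    else:
                        raise RuntimeError(
                            f"trial {t}: no scatter met the optimal-length constraint"
                        )
                trials.append(finalize(session_pts.copy(), t))

    else:  # low: fresh, displaced placement every trial
        prev: PelletDistribution | None = None
        for t in range(1, n_trials + 1):
            for _ in range(max_attempts):
                cand = make_cluster_trial(
                    arena,
                    rng,
                    n_clusters=n_clusters,
                    pellets_per_cluster_range=pellets_per_cluster_range,
                    cluster_sd_cm=cluster_sd_cm,
                    preset=preset,
                    trial_index=t,
                )
                if prev is not None:
                    shifts = across_trial_min_distance(cand, prev)
                    if min(shifts) < min_shift_cm:
                        continue
                if accepted(cand):
                    break
            else:
                raise RuntimeError(
                    f"trial {t}: no placement met the shift and length constraints"
                )
            final = finalize(cand.points, t)
            trials.append(final)
            prev = final

    seq = DistributionSequence(
        arena=arena,
        trials=trials,
        trials_per_session=trials_per_session,
        level=level,
        seed=seed,
    )
    seq.validate()
    return seq


# ---------------------------------------------------------------------------
# predictability metrics
# ---------------------------------------------------------------------------

def across_trial_min_distance(
    current: PelletDistribution, previous: PelletDistribution
) -> np.ndarray:
    """Per-pellet minimum distance (cm) from the current trial's pellets to
    all pellets of the immediately previous trial."""
    if previous.n_pellets == 0:
        raise ValueError("previous distribution is empty")
    return cdist(current.points, previous.points).min(axis=1)


def smooth_density(
    points: PelletDistribution | Iterable[PelletDistribution],
    arena: Arena,
    width_cm: float = 1.0,
) -> ScalarField:
    """Smoothed, normalized pellet density on the arena grid.

    Pellet counts per cell are convolved with a box (averaging) filter of
    the given width, then floored with a small pseudocount and normalized
    to sum to one.  Widths below one grid cell round up to a single cell
    (identity smoothing on this grid).
    """
    if width_cm <= 0:
        raise ValueError("width_cm must be positive")
    dists = [points] if isinstance(points, PelletDistribution) else list(points)
    if not dists or sum(d.n_pellets for d in dists) == 0:
        raise ValueError("no points to smooth")
    counts = np.zeros(arena.shape, dtype=float)
    for d in dists:
        flat = arena.points_to_flat_cells(d.points)
        np.add.at(counts.ravel(), flat, 1.0)
    size = max(1, round(width_cm / ((arena.cell_dx + arena.cell_dy) / 2)))
    if size % 2 == 0:
        size += 1
    if size > 1:
        counts = uniform_filter(counts, size=size, mode="constant")
    dens = counts / counts.sum()
    dens = np.maximum(dens, DENSITY_FLOOR)
    dens /= dens.sum()
    return ScalarField(values=dens, arena=arena)


def relative_entropy(P: ScalarField, Q: ScalarField, atol: float = 1e-6) -> float:
    """Relative entropy RE(P || Q) = sum_j P(j) log2(P(j)/Q(j)), in bits.

    Both fields must live on the same grid and be normalized; Q must be
    strictly positive (guaranteed by the pseudocount floor of
    :func:`smooth_density`).  Non-negative by Gibbs' inequality.
    """
    if not P.same_grid(Q):
        raise ValueError("fields are on different grids")
    p, q = P.flat, Q.flat
    if abs(p.sum() - 1.0) > atol or abs(q.sum() - 1.0) > atol:
        raise ValueError("fields must be normalized to sum to 1")
    if np.any(q <= 0):
        raise ValueError("Q must be strictly positive (apply the density floor)")
    return float(rel_entr(p, q).sum() / np.log(2.0))


def re_trajectory(seq: DistributionSequence, width_cm: float = 1.0) -> np.ndarray:
    """Per-trial relative entropy of each trial against its pooled history.

    Element ``t - 2`` is RE(P_t || Q_t) where P_t is trial t's smoothed
    density and Q_t pools trials 1..t-1 with equal weight.  Requires at
    least two trials.
    """
    if seq.n_trials < 2:
        raise ValueError("need at least two trials")
    out = np.empty(seq.n_trials - 1)
    for t in range(2, seq.n_trials + 1):
        P = smooth_density(seq.trials[t - 1], seq.arena, width_cm)
        Q = smooth_density(seq.trials[: t - 1], seq.arena, width_cm)
        out[t - 2] = relative_entropy(P, Q)
    return out


def constrain_optimal_length(
    candidate: PelletDistribution,
    target_len_cm: float,
    tol_frac: float,
    solver: Callable | None = None,
    start=None,
) -> bool:
    """Accept a placement iff its optimal open-path length is within
    ``tol_frac`` (relative) of ``target_len_cm``."""
    if start is None:
        start = Arena().start
    solve = solver if solver is not None else optimal_route
    route: AcquisitionSequence = solve(start, candidate)
    return abs(route.length_cm - target_len_cm) <= tol_frac * target_len_cm
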