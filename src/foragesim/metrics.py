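"""Behavioral read-outs on trajectories and acquisition orders.

Covers the route-quality metrics (probability of taking the nearest
pellet, per-pellet excess over a nearest-neighbor ordering), long-range
segment efficiency, and the speed/pause statistics (a pause is any run of
samples with instantaneous speed below 1 cm/s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.ndimage import median_filter

from .distributions import PelletDistribution
from .routes import AcquisitionSequence, nearest_neighbor_route, path_length

__all__ = [
    "Trajectory",
    "SpeedStats",
    "nn_probability",
    "ordering_error",
    "segment_efficiency",
    "speed_and_pauses",
]


@dataclass
class Trajectory:
    """Timestamped positions, e.g. from 120 Hz video tracking."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least two samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.positions.shape != (len(self.times), 2):
            raise ValueError("positions must be (n, 2)")

    def position_at(self, t: float) -> np.ndarray:
        """Linearly interpolated position at time t."""
        x = np.interp(t, self.times, self.positions[:, 0])
        y = np.interp(t, self.times, self.positions[:, 1])
        return np.array([x, y])

    def traveled_between(self, t0: float, t1: float) -> float:
        """Arc length of the trajectory between two times."""
        if t1 < t0:
            raise ValueError("t1 must be >= t0")
        inside = (self.times > t0) & (self.times < t1)
        pts = np.vstack(
            [self.position_at(t0), self.positions[inside], self.position_at(t1)]
        )
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _order_of(acquisition) -> tuple[int, ...]:
    if isinstance(acquisition, AcquisitionSequence):
        return acquisition.order
    return tuple(int(i) for i in acquisition)


def nn_probability(acquisition, pellets: PelletDistribution, start) -> float:
    """Fraction of acquisition steps that took the nearest remaining pellet.

    The reference position for each step is the previously acquired
    pellet's location (the start point for the first step).
    """
    order = _order_of(acquisition)
    if not order:
        raise ValueError("empty acquisition")
    pts = pellets.points
    pos = np.asarray(start, dtype=float)
    remaining = list(range(len(pts)))
    hits = 0
    for k in order:
        d = np.linalg.norm(pts[remaining] - pos, axis=1)
        if np.linalg.norm(pts[k] - pos) <= d.min():
            hits += 1
        remaining.remove(k)
        pos = pts[k]
    return hits / len(order)


def ordering_error(acquisition, pellets: PelletDistribution, start) -> float:
    """Per-pellet path-length excess (cm) of the acquisition order over a
    nearest-neighbor ordering; zero iff the orders realize the same length."""
    order = _order_of(acquisition)
    if not order:
        raise ValueError("empty acquisition")
    la = path_length(start, pellets.points, order)
    nn = nearest_neighbor_route(start, pellets)
    return (la - nn.length_cm) / len(order)


def segment_efficiency(
    trajectory: Trajectory,
    events: Sequence,
    min_dist_cm: float = 40.0,
) -> float:
    """Mean straightness of long inter-reward path segments.

    Events are acquisition times (or (time, pellet) pairs).  For each
    segment — trajectory start to the first reward and then reward to
    reward — whose straight-line displacement exceeds ``min_dist_cm``, the
    efficiency is straight-line length / traveled length; the mean over
    qualifying segments is returned, or NaN when no segment qualifies.
    """
    times = [e[0] if isinstance(e, (tuple, list, np.ndarray)) else float(e) for e in events]
    if not times:
        raise ValueError("no acquisition events")
    if any(t < trajectory.times[0] - 1e-9 or t > trajectory.times[-1] + 1e-9 for t in times):
        raise ValueError("event times fall outside the trajectory timeline")
    bounds = [float(trajectory.times[0])] + [float(t) for t in times]
    effs = []
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        straight = float(
            np.linalg.norm(trajectory.position_at(t1) - trajectory.position_at(t0))
        )
        if straight > min_dist_cm:
            traveled = trajectory.traveled_between(t0, t1)
            effs.append(straight / traveled if traveled > 0 else 1.0)
    return float(np.mean(effs)) if effs else float("nan")


class SpeedStats(NamedTuple):
    mean_speed_cm_s: float
    n_pauses: int
    pause_time_fraction: float


def speed_and_pauses(
    trajectory: Trajectory,
    pause_thresh: float = 1.0,
    median_window: int = 3,
) -> SpeedStats:
    """Mean speed excluding pauses, pause count, and fraction of time paused.

    Instantaneous speed comes from central differences of the positions
    after a short median prefilter (suppresses single-frame tracking
    jitter).  Samples with speed strictly below ``pause_thresh`` form
    pauses (maximal runs); the mean speed is taken over the remaining
    samples and is NaN if every sample is paused.
    """
    t = trajectory.times
    pos = trajectory.positions
    if median_window > 1 and len(t) >= median_window:
        k = median_window if median_window % 2 else median_window + 1
        pos = np.column_stack(
            [
                median_filter(pos[:, 0], size=k, mode="nearest"),
                median_filter(pos[:, 1], size=k, mode="nearest"),
            ]
        )
    vx = np.gradient(pos[:, 0], t)
    vy = np.gradient(pos[:, 1], t)
    speed = np.hypot(vx, vy)
    paused = speed < pause_thresh
    n_pauses = int(np.sum(paused[1:] & ~paused[:-1]) + (1 if paused[0] else 0))
    # per-sample time weights for the pause-time fraction
    dt = np.gradient(t)
    pause_fraction = float(dt[paused].sum() / dt.sum())
    mean_speed = float(speed[~paused].mean()) if (~paused).any() else float("nan")
    return SpeedStats(mean_speed, n_pauses, pause_fraction)
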