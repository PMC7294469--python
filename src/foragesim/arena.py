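"""Arena geometry and discretized scalar fields.

The foraging arena is a 2.5 m x 1 m open field discretized into a fixed
40-row x 80-column occupancy grid.  The grid *shape* (not a nominal cell
size) is the primitive: cell extents are derived as ``length_cm / n_cols``
by ``width_cm / n_rows`` (3.125 x 2.5 cm with the defaults).  The animal
(or agent) enters at the midpoint of the short nest-side wall.

Coordinates are continuous centimeters with the origin at the nest-side
wall corner: x in [0, length_cm] along the long axis, y in [0, width_cm].
Grid indexing is (row, col), row-major, with cell (0, 0) at the origin
corner; distances between grid locations are measured between cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = ["Arena", "ScalarField"]


@dataclass(eq=False)
class Arena:
    """Rectangular foraging arena with a fixed occupancy grid.

    Parameters
    ----------
    length_cm, width_cm
        Arena extent along x and y, in cm.
    n_cols, n_rows
        Grid resolution along x and y.
    start
        Entry point ``(x_cm, y_cm)``; defaults to the midpoint of the
        x = 0 wall.
    """

    length_cm: float = 250.0
    width_cm: float = 100.0
    n_cols: int = 80
    n_rows: int = 40
    start: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.width_cm <= 0:
            raise ValueError("arena extents must be positive")
        if self.n_cols < 2 or self.n_rows < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.start is None:
            self.start = (0.0, self.width_cm / 2.0)
        x0, y0 = self.start
        if not (0 <= x0 <= self.length_cm and 0 <= y0 <= self.width_cm):
            raise ValueError("start point lies outside the arena")

    # -- derived geometry -------------------------------------------------

    @property
    def cell_dx(self) -> float:
        return self.length_cm / self.n_cols

    @property
    def cell_dy(self) -> float:
        return self.width_cm / self.n_rows

    @property
    def cell_diag(self) -> float:
        return float(np.hypot(self.cell_dx, self.cell_dy))

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @cached_property
    def col_centers(self) -> np.ndarray:
        return (np.arange(self.n_cols) + 0.5) * self.cell_dx

    @cached_property
    def row_centers(self) -> np.ndarray:
        return (np.arange(self.n_rows) + 0.5) * self.cell_dy

    @cached_property
    def flat_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, row-major flattened."""
        xs, ys = np.meshgrid(self.col_centers, self.row_centers)
        return xs.ravel(), ys.ravel()

    # -- point/cell conversions -------------------------------------------

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x <= self.length_cm and 0 <= y <= self.width_cm

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Grid cell (row, col) containing a point; boundary points clip inward."""
        col = min(int(x / self.cell_dx), self.n_cols - 1)
        row = min(int(y / self.cell_dy), self.n_rows - 1)
        return max(row, 0), max(col, 0)

    def points_to_flat_cells(self, points: np.ndarray) -> np.ndarray:
        """Row-major flat cell index for each (x, y) row of ``points``."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        cols = np.clip((pts[:, 0] / self.cell_dx).astype(int), 0, self.n_cols - 1)
        rows = np.clip((pts[:, 1] / self.cell_dy).astype(int), 0, self.n_rows - 1)
        return rows * self.n_cols + cols

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return float(self.col_centers[col]), float(self.row_centers[row])

    def snap_to_grid(self, points: np.ndarray) -> np.ndarray:
        """Project points onto the centers of their containing cells."""
        flat = self.points_to_flat_cells(points)
        cx, cy = self.flat_centers
        return np.column_stack([cx[flat], cy[flat]])

    def max_distance_from(self, x: float, y: float) -> float:
        """Largest distance from (x, y) to any cell center (attained at a corner cell)."""
        dx = max(abs(self.col_centers[0] - x), abs(self.col_centers[-1] - x))
        dy = max(abs(self.row_centers[0] - y), abs(self.row_centers[-1] - y))
        return float(np.hypot(dx, dy))


@dataclass(eq=False)
class ScalarField:
    """A value per grid cell, indexed (row, col), tied to its :class:`Arena`."""

    values: np.ndarray
    arena: Arena

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.arena.shape:
            raise ValueError(
                f"field shape {self.values.shape} != grid shape {self.arena.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()

    def sum(self) -> float:
        return float(self.values.sum())

    def max(self) -> float:
        return float(self.values.max())

    def same_grid(self, other: "ScalarField") -> bool:
        return self.values.shape == other.values.shape and (
            self.arena.shape == other.arena.shape
        )
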