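"""Occupancy-grid statistics and Shannon entropy of court trajectories.

The court (default 15 m x 11 m, the official 3-on-3 half-court footprint) is
partitioned into an axis-aligned grid of rectangular cells, 15 divisions along
the endline (x) and 10 along the sideline (y), i.e. cells of roughly
100 cm x 110 cm and ``g = 150`` cells in total.  For each trial and agent the
per-frame cell occupancies are histogrammed, normalized to a probability
vector ``p``, and summarized by the Shannon entropy

    H = -sum_i p_i * log2(p_i)            [bits]

with the standard convention ``0 * log 0 = 0``.  A high H means the agent
spread its time over many cells — movement that is hard for an opponent to
anticipate; H = 0 means the agent never left one cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CourtMetricsError

logger = logging.getLogger(__name__)

#: Roles of the offensive team (entropy is analyzed for these by default).
OFFENSE_ROLES = ("O1", "O2", "O3")
#: Roles of the defensive team.
DEFENSE_ROLES = ("D1", "D2", "D3")
ALL_ROLES = OFFENSE_ROLES + DEFENSE_ROLES


@dataclass(frozen=True)
class CourtGrid:
    """Court dimensions and grid divisions.

    Coordinates use the package-wide convention: origin at one court corner,
    x in [0, width_x] running along the endline, y in [0, depth_y] along the
    sideline.  Cells are half-open rectangles ``[k*w, (k+1)*w)`` except the
    last cell on each axis, which is closed so the far boundary belongs to
    the court.  Cell ids are 1-based, row-major: cell 1 is the (x=0, y=0)
    corner, ids increase along x first.
    """

    width_x: float = 1500.0  # endline length, cm
    depth_y: float = 1100.0  # sideline length, cm
    n_x: int = 15            # divisions along the endline
    n_y: int = 10            # divisions along the sideline

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid must have at least one cell per axis")
        if self.width_x <= 0 or self.depth_y <= 0:
            raise ValueError("court dimensions must be positive")

    @property
    def n_cells(self) -> int:
        """Total number of cells g."""
        return self.n_x * self.n_y

    @property
    def cell_width(self) -> float:
        return self.width_x / self.n_x

    @property
    def cell_depth(self) -> float:
        return self.depth_y / self.n_y

    def cell_index(self, x, y):
        """Map court coordinates (cm) to 1-based row-major cell ids.

        Out-of-bounds coordinates are clamped to the nearest boundary cell
        (and a warning logged) so that every frame contributes to the
        occupancy histogram; NaN coordinates raise ``ValueError``.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("cell_index: NaN coordinate")
        oob = (x < 0) | (x > self.width_x) | (y < 0) | (y > self.depth_y)
        if np.any(oob):
            logger.warning(
                "cell_index: %d of %d points outside the court; clamped to "
                "boundary cells", int(np.sum(oob)), oob.size,
            )
        col = np.clip(np.floor(x / self.cell_width).astype(int), 0, self.n_x - 1)
        row = np.clip(np.floor(y / self.cell_depth).astype(int), 0, self.n_y - 1)
        cell = row * self.n_x + col + 1
        if cell.ndim == 0:
            return int(cell)
        return cell

    def cell_center(self, cell):
        """Court coordinates (cm) of the center of 1-based cell ids."""
        cell = np.asarray(cell, dtype=int)
        if np.any((cell < 1) | (cell > self.n_cells)):
            raise ValueError("cell id out of range")
        row, col = np.divmod(cell - 1, self.n_x)
        x = (col + 0.5) * self.cell_width
        y = (row + 0.5) * self.cell_depth
        return x, y

    def neighbors4(self, cell: int) -> list[int]:
        """In-bounds 4-neighborhood (up/down/left/right) of a cell id."""
        row, col = divmod(int(cell) - 1, self.n_x)
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            r, c = row + dr, col + dc
            if 0 <= r < self.n_y and 0 <= c < self.n_x:
                out.append(r * self.n_x + c + 1)
        return out


@dataclass
class OccupancyDistribution:
    """Per-trial, per-agent cell-occupancy histogram.

    ``counts[i]`` is the number of frames spent in cell ``i+1``;
    ``p = counts / n_frames`` is the normalized occupancy distribution.
    """

    counts: np.ndarray
    n_frames: int = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector over cells")
        if (self.counts < 0).any():
            raise ValueError("negative occupancy count")
        self.n_frames = int(self.counts.sum())
        if self.n_frames == 0:
            raise ValueError("occupancy distribution has no frames")

    @property
    def p(self) -> np.ndarray:
        return self.counts / self.n_frames


def occupancy(x, y, grid: CourtGrid | None = None) -> OccupancyDistribution:
    """Histogram one agent's per-frame positions over the grid cells."""
    grid = grid or CourtGrid()
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if x.size == 0:
        raise ValueError("occupancy: empty trajectory")
    if x.shape != y.shape:
        raise ValueError("occupancy: x and y lengths differ")
    cells = grid.cell_index(x, y)
    counts = np.bincount(np.asarray(cells) - 1, minlength=grid.n_cells)
    return OccupancyDistribution(counts)


def entropy(dist) -> float:
    """Shannon entropy in bits of an occupancy distribution.

    Accepts an :class:`OccupancyDistribution` or any probability vector.
    Zero-probability cells contribute nothing.
    """
    p = dist.p if isinstance(dist, OccupancyDistribution) else np.asarray(dist, dtype=float)
    if p.ndim != 1 or (p < 0).any():
        raise ValueError("entropy: p must be a nonnegative vector")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("entropy: probabilities must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def trial_entropy(x, y, grid: CourtGrid | None = None) -> float:
    """Convenience: occupancy entropy of one trajectory, in bits."""
    return entropy(occupancy(x, y, grid))


def entropy_table(
    data: pd.DataFrame,
    grid: CourtGrid | None = None,
    roles: str | tuple[str, ...] = "offense",
) -> pd.DataFrame:
    """Per-trial, per-agent occupancy entropy for a tracking table.

    Parameters
    ----------
    data
        Validated tracking table (see :mod:`courtmetrics.tracking`).
    grid
        Court grid; defaults to the 15 x 10 = 150-cell grid.
    roles
        ``"offense"`` (default, the analyzed roles), ``"all"``, or an explicit
        tuple of role labels.  Roles absent from the input are skipped.

    Returns
    -------
    Long-format table with columns
    ``condition, session, trial, role, H_bits``.
    """
    grid = grid or CourtGrid()
    if isinstance(roles, str):
        if roles == "offense":
            wanted = OFFENSE_ROLES
        elif roles == "all":
            wanted = ALL_ROLES
        else:
            raise ValueError("roles must be 'offense', 'all', or a tuple of labels")
    else:
        wanted = tuple(roles)
    sub = data[data["role"].isin(wanted)]
    if sub.empty:
        raise CourtMetricsError("entropy_table: no rows for the requested roles")
    records = []
    for (cond, sess, trial, role), g in sub.groupby(
        ["condition", "session", "trial", "role"], sort=True, observed=True
    ):
        records.append(
            {
                "condition": cond,
                "session": int(sess),
                "trial": int(trial),
                "role": role,
                "H_bits": trial_entropy(g["x_cm"].to_numpy(), g["y_cm"].to_numpy(), grid),
            }
        )
    return pd.DataFrame.from_records(records)
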