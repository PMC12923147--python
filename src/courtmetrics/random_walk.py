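"""Grid random-walk null model for occupancy entropy.

Each simulated agent starts in the grid cell containing a real initial
position and, at every 0.05-s frame, moves exactly one cell up, down, left
or right, chosen uniformly at random among the moves that stay on the court
(``resample_feasible``, the default).  An alternative rule
(``stay_if_blocked``) draws among all four directions and stays put when the
draw would leave the court.  Positions are emitted at cell centers; the
occupancy entropy of such a walk upper-bounds what structured play can
produce at equal length, which is why the walk serves as the null condition.

Seeding: one master seed; each (session, trial, role) gets a child generator
derived deterministically from it, so any single trial can be re-simulated
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StructureError
from .occupancy import CourtGrid, OFFENSE_ROLES
from .tracking import FRAME_DT, TRACKING_COLUMNS, validate_tracking

#: Default number of frames of a simulated trial (15 s at 20 fps, t=0..15).
DEFAULT_RW_FRAMES = 301


@dataclass
class RandomWalkConfig:
    """Configuration of the random-walk condition."""

    grid: CourtGrid = field(default_factory=CourtGrid)
    n_frames: int | None = None  # None: match each reference trial, capped
    max_frames: int = DEFAULT_RW_FRAMES
    seed: int = 0
    boundary_rule: str = "resample_feasible"  # or "stay_if_blocked"
    roles: tuple[str, ...] = OFFENSE_ROLES

    def __post_init__(self) -> None:
        if self.n_frames is not None and self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.boundary_rule not in ("resample_feasible", "stay_if_blocked"):
            raise ValueError(f"unknown boundary_rule: {self.boundary_rule}")


def _child_rng(master_seed: int, session: int, trial: int, role: str,
               extra: int | None = None) -> np.random.Generator:
    """Deterministic per-(session, trial, role[, extra]) child generator."""
    role_id = sum(ord(c) for c in role)
    keys = [int(master_seed), int(session), int(trial), role_id]
    if extra is not None:
        keys.append(int(extra))
    ss = np.random.SeedSequence(keys)
    return np.random.default_rng(ss)


def simulate_cells(
    start_cell: int,
    n_frames: int,
    grid: CourtGrid,
    rng: np.random.Generator,
    boundary_rule: str = "resample_feasible",
) -> np.ndarray:
    """Simulate one agent's cell sequence (length ``n_frames``, incl. start).

    On a degenerate 1x1 grid no cardinal move exists and the agent stays in
    its only cell.
    """
    if not 1 <= start_cell <= grid.n_cells:
        raise ValueError("start cell outside the grid")
    cells = np.empty(n_frames, dtype=np.int64)
    cells[0] = start_cell
    cur = int(start_cell)
    for k in range(1, n_frames):
        nbrs = grid.neighbors4(cur)
        if boundary_rule == "resample_feasible":
            if nbrs:
                cur = nbrs[int(rng.integers(len(nbrs)))]
        else:  # stay_if_blocked: draw among all 4 directions, stay when blocked
            row, col = divmod(cur - 1, grid.n_x)
            dr, dc = ((-1, 0), (1, 0), (0, -1), (0, 1))[int(rng.integers(4))]
            r, c = row + dr, col + dc
            if 0 <= r < grid.n_y and 0 <= c < grid.n_x:
                cur = r * grid.n_x + c + 1
        cells[k] = cur
    return cells


def simulate_trial(
    initial_positions: dict[str, tuple[float, float]],
    cfg: RandomWalkConfig,
    session: int = 1,
    trial: int = 1,
    n_frames: int | None = None,
) -> pd.DataFrame:
    """Simulate one random-walk trial for the given roles.

    ``initial_positions`` maps role -> (x_cm, y_cm); each agent starts in the
    cell containing its real initial position and positions are reported at
    cell centers.  Returns rows in the canonical tracking schema with
    ``condition == "random_walk"``.
    """
    grid = cfg.grid
    nf = n_frames or cfg.n_frames or cfg.max_frames
    nf = min(nf, cfg.max_frames)
    frames = np.arange(nf)
    parts = []
    for role in sorted(initial_positions):
        x0, y0 = initial_positions[role]
        if not (0 <= x0 <= grid.width_x and 0 <= y0 <= grid.depth_y):
            raise ValueError(f"initial position of {role} outside the court")
        rng = _child_rng(cfg.seed, session, trial, role)
        cells = simulate_cells(grid.cell_index(x0, y0), nf, grid, rng, cfg.boundary_rule)
        x, y = grid.cell_center(cells)
        parts.append(
            pd.DataFrame(
                {
                    "condition": "random_walk",
                    "session": session,
                    "trial": trial,
                    "role": role,
                    "frame": frames,
                    "t_s": frames * FRAME_DT,
                    "x_cm": x,
                    "y_cm": y,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)[TRACKING_COLUMNS]


def build_random_walk_condition(reference: pd.DataFrame, cfg: RandomWalkConfig) -> pd.DataFrame:
    """Simulate the full random-walk condition mirroring a reference dataset.

    ``reference`` is a tracking table restricted to one real condition
    (normally ``high_expertise``); for every (session, trial) in it, each
    configured role is simulated from that trial's real initial position,
    with a frame count matching the reference trial (capped at
    ``cfg.max_frames``) unless ``cfg.n_frames`` fixes it.  The result mirrors
    the reference's (session, trial, role) structure, so downstream tables
    stay balanced.
    """
    if reference.empty:
        raise StructureError("build_random_walk_condition: empty reference")
    if reference["condition"].nunique() != 1:
        raise StructureError("reference must contain exactly one condition")
    out = []
    for (sess, trial), g in reference.groupby(["session", "trial"], sort=True):
        initial, nf = {}, None
        for role in cfg.roles:
            r0 = g[(g["role"] == role) & (g["frame"] == 0)]
            if r0.empty:
                raise StructureError(
                    f"reference trial s{sess} t{trial} lacks role {role} at frame 0"
                )
            initial[role] = (float(r0["x_cm"].iloc[0]), float(r0["y_cm"].iloc[0]))
            nf = int(g[g["role"] == role]["frame"].max()) + 1
        out.append(
            simulate_trial(
                initial, cfg, session=int(sess), trial=int(trial),
                n_frames=cfg.n_frames or nf,
            )
        )
    return validate_tracking(pd.concat(out, ignore_index=True))
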