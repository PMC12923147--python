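"""Synthetic tracking data with controllable movement diversity.

The generator emulates the structure of a 3-on-3 half-court experiment:
6 agents (offense ``O1 O2 O3``, defense ``D1 D2 D3``) on a 15 m x 11 m
court, 20 fps frames, trials up to 15 s, organized as 3 sessions x 7 trials
per condition.  Movement regimes span the diversity ladder the analysis is
designed to resolve:

``stationary``
    the agent holds a position (plus measurement noise): entropy ~ 0.
``scripted_play``
    the agent runs a waypoint script at constant speed and holds at the last
    waypoint — a single representative coordination pattern.
``play_mixture``
    each trial samples one play from a weighted repertoire — diverse
    coordination, higher occupancy entropy than any single play.
``shadow``
    defenders track their matched attacker at a fixed offset toward the goal.
``random_walk``
    one grid cell per frame in a random cardinal direction (see
    :mod:`courtmetrics.random_walk`) — the entropy ceiling.

Positional noise is isotropic Gaussian per axis and frame; its scale is
given as a per-axis mean absolute error (default 2.390 cm x 1.557 cm, the
tracking accuracy typical of bird's-eye video pipelines) and converted to a
standard deviation through the half-normal relation  sd = mae * sqrt(pi/2).

Real players do not hold a scripted line exactly: they adjust, feint and
reposition continuously.  Scripted regimes therefore support an optional
smooth "wander" — a per-axis Ornstein-Uhlenbeck displacement around the
scripted path (amplitude ``wander_sd`` cm, correlation time ``wander_tau_s``
s) — which spreads a trial's occupancy over a realistic number of grid
cells.  It defaults to zero so that scripted kinematics are exact unless a
design switches it on (the bundled default design does).

A second generator, :func:`generate_entropy_table`, skips trajectories
entirely and draws per-trial entropy outcomes directly from the linear mixed
model (condition x role cell means + session and session:trial random
intercepts + residual); it exists for parameter-recovery testing of the
statistics module.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occupancy import ALL_ROLES, OFFENSE_ROLES, CourtGrid
from .random_walk import RandomWalkConfig, _child_rng, build_random_walk_condition, simulate_cells
from .tracking import CONDITION_ORDER, FRAME_DT, TRACKING_COLUMNS, validate_tracking

#: Goal position (cm): centre of the endline, backboard-distance into the court.
GOAL_XY = (750.0, 160.0)

#: Default per-axis mean absolute positional error (cm).
DEFAULT_NOISE_MAE = (2.390, 1.557)

#: sd = mae * sqrt(pi/2) for centred Gaussian noise.
MAE_TO_SD = math.sqrt(math.pi / 2.0)

#: Nominal starting positions (cm): O1 guard, O2 wing, O3 weak-side wing.
START_XY = {"O1": (750.0, 700.0), "O2": (1150.0, 500.0), "O3": (350.0, 500.0)}

#: Waypoint scripts (cm) for the key role's coordination patterns plus the
#: on-ball (O1) and screening (O2) routines used by the default design.
PLAY_WAYPOINTS = {
    "stay_in_place": [(350.0, 500.0)],
    "hand_off": [(350.0, 500.0), (700.0, 680.0), (850.0, 600.0), (950.0, 380.0)],
    "pick_and_roll": [(350.0, 500.0), (680.0, 640.0), (800.0, 560.0), (720.0, 300.0)],
    "deep_corner": [(350.0, 500.0), (220.0, 260.0), (130.0, 130.0)],
    "goal_cut": [(350.0, 500.0), (580.0, 420.0), (740.0, 230.0)],
    "drive_middle": [(750.0, 700.0), (740.0, 460.0), (700.0, 260.0)],
    "screen_and_pop": [(1150.0, 500.0), (930.0, 600.0), (820.0, 540.0), (1020.0, 420.0)],
}


@dataclass
class RegimeSpec:
    """Movement regime of one agent in one condition."""

    regime: str  # stationary | scripted_play | play_mixture | shadow | random_walk
    waypoints: list[tuple[float, float]] | None = None
    speed: float = 250.0               # cm/s along the waypoint script
    plays: list[str] | None = None     # play names for play_mixture
    weights: list[float] | None = None
    noise_mae: tuple[float, float] = DEFAULT_NOISE_MAE
    duration_s: float = 15.0
    waypoint_jitter_cm: float = 30.0   # per-trial waypoint perturbation sd
    speed_jitter: float = 0.08         # per-trial lognormal sigma on speed
    wander_sd: float = 0.0             # OU wander amplitude around the path, cm
    wander_tau_s: float = 2.0          # OU correlation time, s
    target_role: str | None = None     # for shadow
    offset_cm: float = 80.0            # shadow offset toward the goal

    def __post_init__(self) -> None:
        if self.regime not in ("stationary", "scripted_play", "play_mixture", "shadow", "random_walk"):
            raise ValueError(f"unknown regime: {self.regime}")
        if self.duration_s <= 0 or self.duration_s > 15.0:
            raise ValueError("duration_s must be in (0, 15]")
        if self.regime in ("scripted_play", "stationary") and not self.waypoints:
            raise ValueError(f"{self.regime} needs waypoints")
        if self.regime == "play_mixture":
            if not self.plays:
                raise ValueError("play_mixture needs plays")
            w = self.weights or [1.0 / len(self.plays)] * len(self.plays)
            if len(w) != len(self.plays) or not math.isclose(sum(w), 1.0, rel_tol=1e-9):
                raise ValueError("mixture weights must match plays and sum to 1")
            self.weights = list(w)
        if self.regime == "shadow" and not self.target_role:
            raise ValueError("shadow needs target_role")
        if self.speed <= 0:
            raise ValueError("speed must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / FRAME_DT)) + 1


@dataclass
class ExperimentDesign:
    """Balanced multi-condition design: per-condition regime per role."""

    conditions: dict[str, dict[str, RegimeSpec]]
    n_sessions: int = 3
    trials_per_session: int = 7
    seed: int = 0
    grid: CourtGrid = field(default_factory=CourtGrid)


def _check_on_court(points, grid: CourtGrid) -> None:
    for x, y in points:
        if not (0 <= x <= grid.width_x and 0 <= y <= grid.depth_y):
            raise ValueError(f"waypoint ({x}, {y}) outside the court")


def _scripted_path(waypoints, speed: float, n_frames: int) -> np.ndarray:
    """Constant-speed piecewise-linear path through waypoints; holds at the end."""
    wp = np.asarray(waypoints, dtype=float)
    if len(wp) == 1:
        return np.repeat(wp, n_frames, axis=0)
    seg = np.diff(wp, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    t = np.arange(n_frames) * FRAME_DT
    s = np.minimum(t * speed, cum[-1])  # arc length travelled, capped at the end
    xs = np.interp(s, cum, wp[:, 0])
    ys = np.interp(s, cum, wp[:, 1])
    return np.column_stack([xs, ys])


def _jitter_waypoints(wp, sd: float, rng: np.random.Generator, grid: CourtGrid) -> np.ndarray:
    wp = np.asarray(wp, dtype=float)
    if sd <= 0:
        return wp
    out = wp + rng.normal(0.0, sd, size=wp.shape)
    out[:, 0] = np.clip(out[:, 0], 0.0, grid.width_x)
    out[:, 1] = np.clip(out[:, 1], 0.0, grid.depth_y)
    return out


def _ou_wander(n_frames: int, sd: float, tau_s: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck displacement, per axis (n, 2), in cm."""
    if sd <= 0:
        return np.zeros((n_frames, 2))
    a = math.exp(-FRAME_DT / tau_s)
    innov_sd = sd * math.sqrt(1.0 - a * a)
    w = np.empty((n_frames, 2))
    w[0] = rng.normal(0.0, sd, 2)
    eps = rng.normal(0.0, innov_sd, (n_frames - 1, 2))
    for k in range(1, n_frames):
        w[k] = a * w[k - 1] + eps[k - 1]
    return w


def _shadow_path(target_path: np.ndarray, offset_cm: float) -> np.ndarray:
    """Defender path: the attacker's path displaced toward the goal."""
    goal = np.asarray(GOAL_XY)
    vec = goal[None, :] - target_path
    norm = np.linalg.norm(vec, axis=1, keepdims=True)
    norm[norm < 1e-9] = 1.0
    return target_path + vec / norm * offset_cm


def generate_trial(
    specs: dict[str, RegimeSpec],
    seed: int,
    condition: str = "high_expertise",
    session: int = 1,
    trial: int = 1,
    grid: CourtGrid | None = None,
) -> pd.DataFrame:
    """Generate one trial's trajectories for the given roles.

    Attackers are generated first so that ``shadow`` defenders can track the
    attacker's noiseless path; Gaussian noise is then added per frame and
    axis.  All waypoints must lie on the court.
    """
    grid = grid or CourtGrid()
    n_frames = max(s.n_frames for s in specs.values())
    frames = np.arange(n_frames)
    clean_paths: dict[str, np.ndarray] = {}

    cond_token = zlib.crc32(condition.encode()) % (2**31)

    def _wandered(path: np.ndarray, spec: RegimeSpec, rng) -> np.ndarray:
        path = path + _ou_wander(len(path), spec.wander_sd, spec.wander_tau_s, rng)
        path[:, 0] = np.clip(path[:, 0], 0.0, grid.width_x)
        path[:, 1] = np.clip(path[:, 1], 0.0, grid.depth_y)
        return path

    def _make(role: str) -> np.ndarray:
        spec = specs[role]
        rng = _child_rng(seed, session, trial, role, cond_token)
        if spec.regime in ("stationary", "scripted_play"):
            _check_on_court(spec.waypoints, grid)
            wp = _jitter_waypoints(spec.waypoints, spec.waypoint_jitter_cm, rng, grid)
            speed = spec.speed * float(np.exp(rng.normal(0.0, spec.speed_jitter)))
            return _wandered(_scripted_path(wp, speed, n_frames), spec, rng)
        if spec.regime == "play_mixture":
            name = spec.plays[int(rng.choice(len(spec.plays), p=spec.weights))]
            wp = _jitter_waypoints(PLAY_WAYPOINTS[name], spec.waypoint_jitter_cm, rng, grid)
            speed = spec.speed * float(np.exp(rng.normal(0.0, spec.speed_jitter)))
            return _wandered(_scripted_path(wp, speed, n_frames), spec, rng)
        if spec.regime == "random_walk":
            start = spec.waypoints[0] if spec.waypoints else START_XY.get(role, (grid.width_x / 2, grid.depth_y / 2))
            _check_on_court([start], grid)
            cells = simulate_cells(grid.cell_index(*start), n_frames, grid, rng)
            x, y = grid.cell_center(cells)
            return np.column_stack([x, y])
        # shadow
        if spec.target_role not in clean_paths:
            clean_paths[spec.target_role] = _make(spec.target_role)
        return _shadow_path(clean_paths[spec.target_role], spec.offset_cm)

    # attackers (and any non-shadow) first, shadows second
    for role in sorted(specs, key=lambda r: specs[r].regime == "shadow"):
        if role not in clean_paths:
            clean_paths[role] = _make(role)

    parts = []
    for role in sorted(specs):
        spec = specs[role]
        rng_noise = _child_rng(seed ^ 0x5EED, session, trial, role, cond_token)
        path = clean_paths[role].copy()
        sds = (spec.noise_mae[0] * MAE_TO_SD, spec.noise_mae[1] * MAE_TO_SD)
        if spec.regime != "random_walk":  # the null model emits exact cell centers
            path[:, 0] += rng_noise.normal(0.0, sds[0], n_frames) if sds[0] > 0 else 0.0
            path[:, 1] += rng_noise.normal(0.0, sds[1], n_frames) if sds[1] > 0 else 0.0
        parts.append(
            pd.DataFrame(
                {
                    "condition": condition,
                    "session": session,
                    "trial": trial,
                    "role": role,
                    "frame": frames,
                    "t_s": frames * FRAME_DT,
                    "x_cm": path[:, 0],
                    "y_cm": path[:, 1],
                }
            )
        )
    return pd.concat(parts, ignore_index=True)[TRACKING_COLUMNS]


def generate_experiment(design: ExperimentDesign) -> pd.DataFrame:
    """Generate a full balanced experiment from a design.

    A condition whose every role uses the ``random_walk`` regime is built by
    mirroring the generated ``high_expertise`` condition (same sessions,
    trials and frame counts, walks starting from the real initial cells) when
    that condition is present — the construction the analysis uses as its
    null.  Deterministic under ``design.seed``.
    """
    datasets = []
    rw_conditions = []
    for cond, specs in design.conditions.items():
        if all(s.regime == "random_walk" for s in specs.values()) and "high_expertise" in design.conditions:
            rw_conditions.append((cond, specs))
            continue
        for sess in range(1, design.n_sessions + 1):
            for trial in range(1, design.trials_per_session + 1):
                datasets.append(
                    generate_trial(
                        specs, design.seed, condition=cond, session=sess,
                        trial=trial, grid=design.grid,
                    )
                )
    data = pd.concat(datasets, ignore_index=True)
    for cond, specs in rw_conditions:
        ref = data[data["condition"] == "high_expertise"]
        cfg = RandomWalkConfig(grid=design.grid, seed=design.seed, roles=tuple(sorted(specs)))
        rw = build_random_walk_condition(ref, cfg)
        rw = rw.assign(condition=cond) if cond != "random_walk" else rw
        data = pd.concat([data, rw], ignore_index=True)
    return validate_tracking(data)


def default_design(seed: int = 0, duration_s: float = 15.0) -> ExperimentDesign:
    """The default four-condition design used for end-to-end analyses.

    * ``high_expertise`` — on-ball drive (O1), screen-and-pop (O2), and a
      diverse play repertoire for the key role O3 (hand-off, pick-and-roll,
      deep corner, goal cut, stay-in-place).
    * ``low_before_tips`` — same structure, slightly less diverse repertoire
      and sloppier execution (larger waypoint jitter).
    * ``low_after_tips`` — O3 locked to the single coached pattern
      (deep-corner run): a representative coordination pattern, lower
      movement diversity.
    * ``random_walk`` — every agent walks the grid; the entropy ceiling.
    """
    wander = 90.0  # cm; occupancy spread comparable to live half-court play

    def offense(o3: RegimeSpec, jitter: float) -> dict[str, RegimeSpec]:
        d = {
            "O1": RegimeSpec("scripted_play", waypoints=PLAY_WAYPOINTS["drive_middle"],
                             duration_s=duration_s, waypoint_jitter_cm=jitter,
                             wander_sd=wander),
            "O2": RegimeSpec("scripted_play", waypoints=PLAY_WAYPOINTS["screen_and_pop"],
                             duration_s=duration_s, waypoint_jitter_cm=jitter,
                             wander_sd=wander),
            "O3": o3,
        }
        for k in ("1", "2", "3"):
            d[f"D{k}"] = RegimeSpec("shadow", target_role=f"O{k}", duration_s=duration_s)
        return d

    diverse = RegimeSpec(
        "play_mixture",
        plays=["hand_off", "pick_and_roll", "deep_corner", "goal_cut", "stay_in_place"],
        weights=[0.25, 0.25, 0.2, 0.2, 0.1],
        duration_s=duration_s, wander_sd=wander,
    )
    semi_diverse = RegimeSpec(
        "play_mixture",
        plays=["hand_off", "pick_and_roll", "deep_corner", "stay_in_place"],
        weights=[0.3, 0.3, 0.3, 0.1],
        duration_s=duration_s, waypoint_jitter_cm=45.0, wander_sd=wander,
    )
    coached = RegimeSpec(
        "scripted_play", waypoints=PLAY_WAYPOINTS["deep_corner"], duration_s=duration_s,
        wander_sd=wander * 0.7,  # coached pattern executed more tightly
    )
    rw = {r: RegimeSpec("random_walk", duration_s=duration_s) for r in ALL_ROLES}
    return ExperimentDesign(
        conditions={
            "low_before_tips": offense(semi_diverse, 45.0),
            "low_after_tips": offense(coached, 30.0),
            "high_expertise": offense(diverse, 30.0),
            "random_walk": rw,
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# direct outcome-level generator (for parameter recovery of the stats module)
# ---------------------------------------------------------------------------

#: Treatment-coded generative coefficients on the entropy (bits) scale used
#: as defaults; baselines low_before_tips and O1.
DEFAULT_ENTROPY_COEFS = {
    "intercept": 3.431,
    "cond": {"low_after_tips": -0.023, "high_expertise": 0.196, "random_walk": 1.626},
    "role": {"O2": 0.320, "O3": -0.867},
    "interaction": {
        ("low_after_tips", "O2"): 0.262,
        ("high_expertise", "O2"): -0.629,
        ("random_walk", "O2"): -0.448,
        ("low_after_tips", "O3"): -0.345,
        ("high_expertise", "O3"): 0.142,
        ("random_walk", "O3"): 0.944,
    },
}

#: Default variance components on the entropy scale.
DEFAULT_ENTROPY_VARIANCES = {"session": 0.008, "session_trial": 0.033, "residual": 0.565}


def cell_means_from_coefs(coefs: dict | None = None,
                          conditions=CONDITION_ORDER,
                          roles=OFFENSE_ROLES) -> dict[tuple[str, str], float]:
    """Expand treatment-coded coefficients into condition x role cell means."""
    c = coefs or DEFAULT_ENTROPY_COEFS
    out = {}
    for cond in conditions:
        for role in roles:
            mu = c["intercept"]
            mu += c["cond"].get(cond, 0.0)
            mu += c["role"].get(role, 0.0)
            mu += c["interaction"].get((cond, role), 0.0)
            out[(cond, role)] = mu
    return out


def generate_entropy_table(
    cell_means: dict[tuple[str, str], float] | None = None,
    var_session: float = DEFAULT_ENTROPY_VARIANCES["session"],
    var_trial: float = DEFAULT_ENTROPY_VARIANCES["session_trial"],
    var_resid: float = DEFAULT_ENTROPY_VARIANCES["residual"],
    n_sessions: int = 3,
    trials_per_session: int = 7,
    seed: int = 0,
    conditions=CONDITION_ORDER,
    roles=OFFENSE_ROLES,
) -> pd.DataFrame:
    """Draw per-trial entropy outcomes directly from the mixed model.

    H_{c,r,s,t} = mu_{c,r} + u_s + v_{s,t} + e  with
    u_s ~ N(0, var_session), v_{s,t} ~ N(0, var_trial),
    e ~ N(0, var_resid).  Session and session:trial effects are shared across
    conditions and roles, mirroring how the comparison model groups the data.
    With all variances zero the outcomes equal the cell means exactly.
    """
    if min(var_session, var_trial, var_resid) < 0:
        raise ValueError("variances must be nonnegative")
    mus = cell_means if cell_means is not None else cell_means_from_coefs()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE7]))
    u = rng.normal(0.0, math.sqrt(var_session), n_sessions)
    v = rng.normal(0.0, math.sqrt(var_trial), (n_sessions, trials_per_session))
    records = []
    for cond in conditions:
        for role in roles:
            for s in range(n_sessions):
                for t in range(trials_per_session):
                    e = rng.normal(0.0, math.sqrt(var_resid))
                    records.append(
                        {
                            "condition": cond,
                            "session": s + 1,
                            "trial": t + 1,
                            "role": role,
                            "H_bits": mus[(cond, role)] + u[s] + v[s, t] + e,
                        }
                    )
    return pd.DataFrame.from_records(records)
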