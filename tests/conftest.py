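import numpy as np
import pandas as pd
import pytest

from courtmetrics.tracking import FRAME_DT, TRACKING_COLUMNS


def make_tracking(
    trajectories: dict,
    condition: str = "high_expertise",
    session: int = 1,
    trial: int = 1,
) -> pd.DataFrame:
    """Build a tracking table from {role: [(x, y), ...]} for one trial."""
    rows = []
    for role, pts in trajectories.items():
        for frame, (x, y) in enumerate(pts):
            rows.append(
                {
                    "condition": condition, "session": session, "trial": trial,
                    "role": role, "frame": frame, "t_s": frame * FRAME_DT,
                    "x_cm": float(x), "y_cm": float(y),
                }
            )
    return pd.DataFrame(rows)[TRACKING_COLUMNS]


def random_tracking(
    rng: np.random.Generator,
    roles=("O1", "O2", "O3", "D1", "D2", "D3"),
    n_frames: int = 20,
    conditions=("high_expertise",),
    n_sessions: int = 1,
    n_trials: int = 1,
) -> pd.DataFrame:
    """Random (uniform on the court) multi-trial tracking table."""
    parts = []
    for cond in conditions:
        for s in range(1, n_sessions + 1):
            for t in range(1, n_trials + 1):
                traj = {
                    role: np.column_stack(
                        [rng.uniform(0, 1500, n_frames), rng.uniform(0, 1100, n_frames)]
                    )
                    for role in roles
                }
                parts.append(make_tracking(traj, condition=cond, session=s, trial=t))
    return pd.concat(parts, ignore_index=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240925)


@pytest.fixture(scope="session")
def default_experiment():
    """One full default-design synthetic experiment, shared across tests."""
    from courtmetrics.synthetic import default_design, generate_experiment

    return generate_experiment(default_design(seed=11))
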