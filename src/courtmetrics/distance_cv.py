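"""Coefficient of variation of pairwise distances to the key offensive role.

For each trial, the Euclidean distance between the key player (offensive #3,
the intervention-decision-and-adjustment role) and each of the five other
agents is computed frame by frame.  The coefficient of variation

    CV = sd(d) / mean(d)

(sample standard deviation, n-1 denominator) summarizes how variable that
spacing was relative to its average: near 0 for a fixed spacing (stationary
play or orbiting at fixed radius), large when the key player alternates
between tight two-man actions and deep spacing.  The simulated random-walk
condition is excluded from this analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateInputError, SchemaError

#: Partners paired with the key role, in reporting order.
PAIR_PARTNERS = ("O1", "O2", "D1", "D2", "D3")

#: Condition excluded from the CV analysis (simulation has no real defenders).
CV_EXCLUDED_CONDITIONS = ("random_walk",)


def distance_series(trial_track: pd.DataFrame, role_a: str, role_b: str) -> np.ndarray:
    """Frame-wise Euclidean distance (cm) between two roles in one trial."""
    a = trial_track[trial_track["role"] == role_a].sort_values("frame")
    b = trial_track[trial_track["role"] == role_b].sort_values("frame")
    if a.empty or b.empty:
        raise SchemaError(f"distance_series: role {role_a if a.empty else role_b} absent")
    if not np.array_equal(a["frame"].to_numpy(), b["frame"].to_numpy()):
        raise AlignmentError(f"distance_series: frames of {role_a} and {role_b} misaligned")
    return np.hypot(
        a["x_cm"].to_numpy() - b["x_cm"].to_numpy(),
        a["y_cm"].to_numpy() - b["y_cm"].to_numpy(),
    )


def coefficient_of_variation(d: np.ndarray) -> tuple[float, float, float]:
    """(mean, sample sd, cv) of a distance series.

    Requires at least 2 frames and a strictly positive mean; a pair of agents
    coincident throughout the trial has no meaningful relative variability.
    """
    d = np.asarray(d, dtype=float)
    if d.size < 2:
        raise DegenerateInputError("coefficient_of_variation: need at least 2 frames")
    mean = float(d.mean())
    if mean <= 0:
        raise DegenerateInputError("coefficient_of_variation: zero mean distance")
    sd = float(d.std(ddof=1))
    return mean, sd, sd / mean


def cv_table(
    data: pd.DataFrame,
    key_role: str = "O3",
    partners: tuple[str, ...] = PAIR_PARTNERS,
    exclude_conditions: tuple[str, ...] = CV_EXCLUDED_CONDITIONS,
) -> pd.DataFrame:
    """Per-trial CV of the distance between the key role and each partner.

    Returns a long-format table with columns
    ``condition, session, trial, pair, mean_cm, sd_cm, cv`` — one row per
    (trial, partner), five per trial by default.
    """
    sub = data[~data["condition"].isin(exclude_conditions)]
    records = []
    for (cond, sess, trial), g in sub.groupby(
        ["condition", "session", "trial"], sort=True, observed=True
    ):
        present = set(g["role"].unique())
        needed = {key_role, *partners}
        if not needed <= present:
            raise SchemaError(
                f"cv_table: trial {cond} s{sess} t{trial} missing role(s) "
                f"{sorted(needed - present)}"
            )
        for other in partners:
            d = distance_series(g, key_role, other)
            mean, sd, cv = coefficient_of_variation(d)
            records.append(
                {
                    "condition": cond,
                    "session": int(sess),
                    "trial": int(trial),
                    "pair": f"{key_role}-{other}",
                    "mean_cm": mean,
                    "sd_cm": sd,
                    "cv": cv,
                }
            )
    return pd.DataFrame.from_records(records)
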