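"""Reading, validating and writing multi-agent tracking tables.

A tracking table is an ordinary :class:`pandas.DataFrame` in long format with
one row per (agent, frame):

========== ===================================================================
column      meaning
========== ===================================================================
condition   one of ``high_expertise, low_before_tips, low_after_tips,
            random_walk``
session     session number (1-3)
trial       trial number within the session (1-7)
role        agent label: offense ``O1 O2 O3``, defense ``D1 D2 D3``
frame       0-based frame index at 20 fps
t_s         time in seconds, ``frame * 0.05``
x_cm        position along the endline axis (0-1500 cm by default)
y_cm        position along the sideline axis (0-1100 cm by default)
========== ===================================================================

Frames within a trial must be consecutive from 0 and a trial may not exceed
302 frames (the 15-s play limit at 20 fps).  The module also estimates the
projective (homography) transform from camera pixels to court centimetres
from point correspondences, and reports per-axis positional error between
two tracking tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, CalibrationError, IntegrityError, SchemaError

#: Canonical column order of a tracking table.
TRACKING_COLUMNS = ["condition", "session", "trial", "role", "frame", "t_s", "x_cm", "y_cm"]

#: Recognized condition labels.
CONDITIONS = ("high_expertise", "low_before_tips", "low_after_tips", "random_walk")

#: Display / baseline ordering of conditions used throughout the package.
CONDITION_ORDER = ("low_before_tips", "low_after_tips", "high_expertise", "random_walk")

FRAME_DT = 0.05         # seconds per frame (20 fps)
MAX_TRIAL_FRAMES = 302  # 15.05 s at 20 fps

_TRIAL_KEY = ["condition", "session", "trial"]


def validate_tracking(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a tracking table and return it sorted canonically.

    Raises
    ------
    SchemaError
        if a required column is missing or a label is unrecognized.
    IntegrityError
        if (trial, role, frame) keys are duplicated, frames are not
        consecutive from 0, t_s disagrees with frame, or a trial is too long.
    """
    missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"tracking table missing column(s): {', '.join(missing)}")
    df = df.loc[:, TRACKING_COLUMNS].copy()
    bad_cond = set(df["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise SchemaError(f"unrecognized condition label(s): {sorted(bad_cond)}")
    for col in ("session", "trial", "frame"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    for col in ("t_s", "x_cm", "y_cm"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    if df[["x_cm", "y_cm"]].isna().any().any():
        raise IntegrityError("tracking table contains NaN coordinates")

    key = _TRIAL_KEY + ["role", "frame"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise IntegrityError(f"duplicate (trial, role, frame) row: {first}")

    df = df.sort_values(key, kind="mergesort").reset_index(drop=True)
    for (cond, sess, trial, role), g in df.groupby(_TRIAL_KEY + ["role"], sort=False):
        frames = g["frame"].to_numpy()
        if frames[0] != 0 or not np.array_equal(frames, np.arange(len(frames))):
            raise IntegrityError(
                f"frames not consecutive from 0 for {cond} s{sess} t{trial} {role}"
            )
        if len(frames) > MAX_TRIAL_FRAMES:
            raise IntegrityError(
                f"trial {cond} s{sess} t{trial} {role} exceeds {MAX_TRIAL_FRAMES} frames"
            )
        if not np.allclose(g["t_s"].to_numpy(), frames * FRAME_DT, atol=1e-6):
            raise IntegrityError(
                f"t_s inconsistent with frame*{FRAME_DT} for {cond} s{sess} t{trial} {role}"
            )
    return df


def read_tracking(path, format: str | None = None) -> pd.DataFrame:
    """Read a tracking table from CSV (canonical) or XLSX and validate it.

    ``format`` is inferred from the file suffix when not given.  Lines
    starting with ``#`` in CSV files are treated as comments (the pipeline
    writes provenance headers that way).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tracking file not found: {path}")
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    elif fmt == "xlsx":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown format: {fmt}")
    return validate_tracking(df)


def write_tracking(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a tracking table as canonical CSV (lossless float round-trip)."""
    path = Path(path)
    df = df.loc[:, TRACKING_COLUMNS]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def positional_error(est: pd.DataFrame, ref: pd.DataFrame) -> tuple[float, float]:
    """Per-axis mean absolute error (cm) between two tracking tables.

    Both tables must contain exactly the same (condition, session, trial,
    role, frame) keys.  Symmetric in its arguments.
    """
    key = _TRIAL_KEY + ["role", "frame"]
    a = est.set_index(key)[["x_cm", "y_cm"]].sort_index()
    b = ref.set_index(key)[["x_cm", "y_cm"]].sort_index()
    if not a.index.equals(b.index):
        raise AlignmentError("positional_error: (trial, role, frame) keys differ")
    d = (a - b).abs().mean()
    return float(d["x_cm"]), float(d["y_cm"])


# ---------------------------------------------------------------------------
# pixel -> court projective (homography) calibration
# ---------------------------------------------------------------------------

@dataclass
class ProjectiveTransform:
    """3x3 homogeneous map from image pixels to court centimetres.

    The matrix is normalized so its bottom-right entry is 1.
    ``residuals_cm`` holds the per-point calibration residuals (cm) from
    fitting, when the transform was estimated from correspondences.
    """

    matrix: np.ndarray
    residuals_cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        H = np.asarray(self.matrix, dtype=float)
        if H.shape != (3, 3):
            raise ValueError("projective matrix must be 3x3")
        if abs(H[2, 2]) < 1e-12 or not np.isfinite(np.linalg.cond(H)) :
            raise ValueError("projective matrix is singular or not normalizable")
        self.matrix = H / H[2, 2]

    def __call__(self, pts) -> np.ndarray:
        return apply_transform(self, pts)

    def inverse(self) -> "ProjectiveTransform":
        return ProjectiveTransform(np.linalg.inv(self.matrix))


def fit_projective_transform(pixel_pts, court_pts) -> ProjectiveTransform:
    """Least-squares direct-linear-transform fit of pixels -> court cm.

    Requires at least 4 correspondences, no 3 of which may make the
    configuration degenerate (e.g. all collinear).  Uses the normalized DLT
    of scikit-image.
    """
    from skimage.transform import ProjectiveTransform as _SkProjective

    px = np.asarray(pixel_pts, dtype=float)
    cc = np.asarray(court_pts, dtype=float)
    if px.ndim != 2 or px.shape[1] != 2 or px.shape != cc.shape:
        raise CalibrationError("correspondences must be matching (n, 2) arrays")
    if len(px) < 4:
        raise CalibrationError("projective calibration needs at least 4 points")
    if hasattr(_SkProjective, "from_estimate"):
        tf = _SkProjective.from_estimate(px, cc)
        ok = bool(tf)
    else:  # older scikit-image API
        tf = _SkProjective()
        ok = bool(tf.estimate(px, cc))
    H = tf.params if ok else None
    if not ok or not np.all(np.isfinite(H)) or abs(np.linalg.det(H)) < 1e-12:
        raise CalibrationError("degenerate point configuration for calibration")
    out = ProjectiveTransform(H)
    mapped = out(px)
    out.residuals_cm = np.linalg.norm(mapped - cc, axis=1)
    return out


def apply_transform(T: ProjectiveTransform, pts) -> np.ndarray:
    """Apply a projective transform (homogeneous projection + perspective division)."""
    pts = np.asarray(pts, dtype=float)
    single = pts.ndim == 1
    pts2 = np.atleast_2d(pts)
    hom = np.column_stack([pts2, np.ones(len(pts2))])
    out = hom @ T.matrix.T
    w = out[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise FloatingPointError("point maps to the plane at infinity (w ~ 0)")
    res = out[:, :2] / w[:, None]
    return res[0] if single else res


def read_calibration(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a calibration CSV of ``px_x,px_y,court_x_cm,court_y_cm``."""
    df = pd.read_csv(path, comment="#")
    needed = ["px_x", "px_y", "court_x_cm", "court_y_cm"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"calibration file missing column(s): {', '.join(missing)}")
    return df[["px_x", "px_y"]].to_numpy(float), df[["court_x_cm", "court_y_cm"]].to_numpy(float)
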