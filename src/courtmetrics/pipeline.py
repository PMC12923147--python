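"""One-command orchestration: tracking -> entropy + CV -> random-walk
augmentation -> model ladder -> report bundle.

Every output CSV carries a provenance header (seed, config hash); the
``manifest.json`` written alongside suffices to reproduce the run.
Identical config + seed produce byte-identical payloads.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .distance_cv import cv_table
from .errors import CourtMetricsError
from .occupancy import CourtGrid, entropy_table
from .random_walk import RandomWalkConfig, build_random_walk_condition
from .stats import anova_type3, fit_ladder, fit_optimal, pairwise_contrasts
from .synthetic import default_design, generate_experiment
from .tracking import read_tracking, write_tracking

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "input": None,              # tracking CSV/XLSX; None -> synthetic design
    "synthetic": {
        "use_default_design": True,
        "duration_s": 15.0,
        "n_sessions": 3,
        "trials_per_session": 7,
    },
    "court": {"width_cm": 1500.0, "depth_cm": 1100.0},
    "grid": {"nx": 15, "ny": 10},
    "random_walk": {"enabled": True, "boundary_rule": "resample_feasible"},
    "stats": {
        "cond_base": "low_before_tips",
        "entropy_unit_base": "O1",
        "cv_unit_base": "O3-O1",
        "adjust": "bonferroni",
        "alpha": 0.05,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path=None) -> dict:
    cfg = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, cfg)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def run_full(config: dict, seed: int, outdir) -> dict:
    """Run the full analysis pipeline and write the report bundle.

    Returns a manifest dict describing every artifact written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    header = f"courtmetrics {__version__} | seed={seed} | config_sha256={chash}"

    grid = CourtGrid(
        width_x=config["court"]["width_cm"], depth_y=config["court"]["depth_cm"],
        n_x=config["grid"]["nx"], n_y=config["grid"]["ny"],
    )

    if config.get("input"):
        path = Path(config["input"])
        if not path.exists():
            raise CourtMetricsError(f"stage input: tracking file not found: {path}")
        logger.info("reading tracking data from %s", path)
        data = read_tracking(path)
    else:
        logger.info("generating synthetic experiment (default design, seed=%d)", seed)
        syn = config["synthetic"]
        design = default_design(seed=seed, duration_s=syn["duration_s"])
        design.grid = grid
        design.n_sessions = int(syn.get("n_sessions", 3))
        design.trials_per_session = int(syn.get("trials_per_session", 7))
        data = generate_experiment(design)

    rw_cfg = config["random_walk"]
    if rw_cfg.get("enabled", True) and "random_walk" not in set(data["condition"]):
        ref = data[data["condition"] == "high_expertise"]
        if ref.empty:
            raise CourtMetricsError("stage random_walk: no high_expertise reference trials")
        rw = build_random_walk_condition(
            ref, RandomWalkConfig(grid=grid, seed=seed, boundary_rule=rw_cfg["boundary_rule"]),
        )
        data = pd.concat([data, rw], ignore_index=True)

    write_tracking(data, outdir / "tracking.csv", header_comment=header)

    ent = entropy_table(data, grid)
    _write_csv(ent, outdir / "entropy.csv", header)
    cv = cv_table(data)
    _write_csv(cv, outdir / "cv.csv", header)

    st = config["stats"]
    artifacts = {"tracking.csv": None, "entropy.csv": None, "cv.csv": None}
    for outcome_name, table, outcome_col, unit_col, unit_base in (
        ("entropy", ent, "H_bits", "role", st["entropy_unit_base"]),
        ("cv", cv, "cv", "pair", st["cv_unit_base"]),
    ):
        logger.info("fitting model ladder for %s", outcome_name)
        ladder = fit_ladder(table, outcome_col, unit_col)
        _write_csv(ladder.table, outdir / f"model_comparison_{outcome_name}.csv", header)
        opt = fit_optimal(table, outcome_col, unit_col, model=ladder.selected,
                          cond_base=st["cond_base"], unit_base=unit_base)
        fe = opt.fixed_effects()
        _write_csv(fe, outdir / f"fixed_effects_{outcome_name}.csv", header)
        re_rows = pd.DataFrame(
            [{"component": k, "variance": v} for k, v in opt.random_effects().items()]
        )
        _write_csv(re_rows, outdir / f"random_effects_{outcome_name}.csv", header)
        an = anova_type3(table, outcome_col, unit_col)
        _write_csv(an, outdir / f"anova3_{outcome_name}.csv", header)
        inter_p = float(an.loc[an["effect"] == "interaction", "p"].iloc[0])
        if ladder.selected == "interactive" and inter_p < st["alpha"]:
            contr = pairwise_contrasts(opt, adjust=st["adjust"])
            _write_csv(contr, outdir / f"contrasts_{outcome_name}.csv", header)
            artifacts[f"contrasts_{outcome_name}.csv"] = None
        else:
            logger.info(
                "%s: interaction p=%.3f not below alpha or non-interactive model; "
                "per-unit contrasts not emitted", outcome_name, inter_p,
            )
        for nm in ("model_comparison", "fixed_effects", "random_effects", "anova3"):
            artifacts[f"{nm}_{outcome_name}.csv"] = None

    manifest = {
        "package": "courtmetrics",
        "version": __version__,
        "seed": seed,
        "config_sha256": chash,
        "config": config,
        "artifacts": sorted(artifacts),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
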