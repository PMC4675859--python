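"""Reading and writing tracking data, metric tables and result files.

Tracking files are long-format CSV with one row per 10 Hz position
sample: subject_id, group, genotype, treatment, phase, session, trial,
start_point, t_s, x_cm, y_cm (pool-centered cm).  Writing then reading a
simulated cohort reproduces the trajectories exactly; the censoring flag
and goal position are reconstructed from the phase and the geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import PoolGeometry
from .metrics import DensityGrid, OccupancyGrid
from .pca import PCAModel
from .simulate import PHASES, Trajectory

TRACKING_COLUMNS = [
    "subject_id", "group", "genotype", "treatment", "phase", "session",
    "trial", "start_point", "t_s", "x_cm", "y_cm",
]


def write_tracking(trajectories: list[Trajectory], path: str | Path) -> None:
    frames = []
    for tr in trajectories:
        n = len(tr.samples)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [tr.subject_id] * n,
                    "group": [tr.group] * n,
                    "genotype": [tr.genotype] * n,
                    "treatment": [tr.treatment] * n,
                    "phase": [tr.phase] * n,
                    "session": [tr.session] * n,
                    "trial": [tr.trial] * n,
                    "start_point": [tr.start_point] * n,
                    "t_s": tr.samples[:, 0],
                    "x_cm": tr.samples[:, 1],
                    "y_cm": tr.samples[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracking(path: str | Path, geometry: PoolGeometry | None = None) -> list[Trajectory]:
    """Parse a tracking CSV into trajectories, validating the schema.

    Malformed rows are reported with their file line number; positions
    outside the pool are rejected.
    """
    geometry = geometry or PoolGeometry()
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tracking file lacks columns {missing}")
    for col in ("t_s", "x_cm", "y_cm"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"line {bad[0] + 2}: non-numeric {col!r}")
    bad_phase = df.index[~df["phase"].isin(PHASES)]
    if len(bad_phase):
        raise ValueError(
            f"line {bad_phase[0] + 2}: unknown phase {df.loc[bad_phase[0], 'phase']!r}"
        )
    r2 = df["x_cm"] ** 2 + df["y_cm"] ** 2
    out_of_pool = df.index[r2 > geometry.pool_radius**2 + 1e-6]
    if len(out_of_pool):
        i = out_of_pool[0]
        raise ValueError(
            f"line {i + 2}: position ({df.loc[i, 'x_cm']}, {df.loc[i, 'y_cm']}) "
            "outside the pool"
        )
    rev = geometry.reversed()
    trajectories = []
    keys = ["subject_id", "group", "genotype", "treatment", "phase", "session", "trial"]
    for key, sub in df.groupby(keys, sort=False):
        sid, group, gt, tr, phase, session, trial = key
        samples = sub[["t_s", "x_cm", "y_cm"]].to_numpy(dtype=float)
        dts = np.diff(samples[:, 0])
        if len(dts) and (np.any(dts <= 0) or np.ptp(dts) > 1e-6):
            raise ValueError(
                f"non-uniform or non-increasing timestamps for {sid} "
                f"{phase} session {session} trial {trial}"
            )
        if phase == "pretraining":
            goal, present = (0.0, 0.0), True
        elif phase == "reversal":
            goal, present = rev.platform_center, True
        elif phase == "probe":
            goal, present = geometry.platform_center, False
        else:
            goal, present = geometry.platform_center, True
        if present:
            d = np.hypot(samples[:, 1] - goal[0], samples[:, 2] - goal[1])
            censored = bool(d.min() > geometry.platform_radius)
        else:
            censored = True
        trajectories.append(
            Trajectory(
                subject_id=sid, group=group, genotype=gt, treatment=tr,
                phase=phase, session=int(session), trial=int(trial),
                start_point=str(sub["start_point"].iloc[0]), samples=samples,
                censored=censored, goal=tuple(goal), platform_present=present,
            )
        )
    return trajectories


def write_pca_json(model: PCAModel, path: str | Path) -> None:
    payload = {
        "columns": model.columns,
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "percent_variance": model.percent_variance.tolist(),
        "loadings": model.loadings.tolist(),
        "contributions": model.contributions.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_scores_csv(model: PCAModel, path: str | Path) -> None:
    idx = pd.MultiIndex.from_tuples(model.row_labels, names=["group", "session"])
    cols = [f"PC{p + 1}" for p in range(model.n_components)]
    pd.DataFrame(model.scores, index=idx, columns=cols).to_csv(path)


def write_grid(grid: OccupancyGrid | DensityGrid, path: str | Path) -> None:
    """Plain-text matrix plus a JSON sidecar describing edges/levels."""
    path = Path(path)
    if isinstance(grid, OccupancyGrid):
        np.savetxt(path, grid.dwell, fmt="%.6g")
        meta = {
            "kind": "occupancy",
            "x_edges": grid.x_edges.tolist(),
            "y_edges": grid.y_edges.tolist(),
            "total_dwell_s": grid.total_dwell,
            "scope": grid.scope,
        }
    else:
        np.savetxt(path, grid.density, fmt="%.6g")
        meta = {
            "kind": "density",
            "x": [float(grid.x[0]), float(grid.x[-1])],
            "y": [float(grid.y[0]), float(grid.y[-1])],
            "grid_n": int(len(grid.x)),
            "bandwidth": grid.bandwidth,
            "levels": grid.levels.tolist(),
        }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True)
    )
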