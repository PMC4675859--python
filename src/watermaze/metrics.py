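"""Trajectory-derived behavioral metrics.

Seven variables per trial: escape latency (right-censored at the cutoff),
path length, mean swim speed (path length / latency), the Gallagher
proximity index (mean distance to the goal in 1-second block averages),
the Whishaw directness index (% of path inside the straight corridor
joining release point and goal), thigmotaxis (% of samples in the
peripheral band) and % of time in the target quadrant.  Plus occupancy
heat-maps and 2D Gaussian kernel density grids for visual summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import PoolGeometry, quadrant_labels
from .simulate import Trajectory

#: Canonical metric column order used across the package.
METRIC_COLUMNS = [
    "latency",
    "target_quadrant_time",
    "thigmotaxis",
    "whishaw",
    "gallagher",
    "distance",
    "speed",
]

ID_COLUMNS = ["subject_id", "group", "genotype", "treatment", "phase", "session"]


def latency_and_censoring(
    traj: Trajectory, cutoff: float = 60.0
) -> tuple[float, bool]:
    """Time of first platform contact, or the cutoff with ``censored`` True.

    Probe trials (no platform) are censored at the cutoff by convention.
    """
    if len(traj.samples) == 0:
        raise ValueError("empty trajectory")
    if not traj.platform_present:
        return cutoff, True
    d = np.hypot(
        traj.samples[:, 1] - traj.goal[0], traj.samples[:, 2] - traj.goal[1]
    )
    # platform radius is implicit in how the trajectory was recorded; for
    # externally read paths we detect first contact with the default radius
    hit = np.flatnonzero(d <= _platform_radius_of(traj))
    if hit.size == 0:
        return cutoff, True
    return float(traj.samples[hit[0], 0]), False


def _platform_radius_of(traj: Trajectory, default: float = 6.0) -> float:
    return getattr(traj, "platform_radius", default)


def path_length_and_speed(traj: Trajectory, latency: float | None = None) -> tuple[float, float]:
    """Total path length (cm) and mean speed = distance / latency (cm/s)."""
    if len(traj.samples) < 2:
        raise ValueError("need at least two samples for a path length")
    steps = np.hypot(
        np.diff(traj.samples[:, 1]), np.diff(traj.samples[:, 2])
    )
    distance = float(steps.sum())
    if latency is None:
        latency = float(traj.samples[-1, 0])
    speed = distance / latency if latency > 0 else 0.0
    return distance, speed


def gallagher_index(traj: Trajectory, goal: tuple[float, float] | None = None) -> float:
    """Mean distance to the goal, averaged in consecutive 1-second blocks.

    Distances are computed per 10 Hz sample, averaged within blocks of 10
    samples, and the block means are then averaged; a trailing partial
    block is averaged over its own sample count.
    """
    if len(traj.samples) == 0:
        raise ValueError("empty trajectory")
    gx, gy = traj.goal if goal is None else goal
    d = np.hypot(traj.samples[:, 1] - gx, traj.samples[:, 2] - gy)
    block_means = [d[i : i + 10].mean() for i in range(0, len(d), 10)]
    return float(np.mean(block_means))


def whishaw_index(
    traj: Trajectory,
    start: tuple[float, float] | None = None,
    goal: tuple[float, float] | None = None,
    corridor_half_width: float = 12.0,
) -> float:
    """Percentage of path length inside the straight release→goal corridor.

    The corridor is a capsule of the given half-width around the segment;
    a sub-step counts as inside only when both its endpoints are.
    """
    xy = traj.samples[:, 1:3]
    if start is None:
        start = tuple(xy[0])
    if goal is None:
        goal = traj.goal
    a = np.asarray(start, dtype=float)
    b = np.asarray(goal, dtype=float)
    if np.allclose(a, b):
        raise ValueError("release point and goal coincide")
    inside = _dist_to_segment(xy, a, b) <= corridor_half_width
    steps = np.hypot(*(np.diff(xy, axis=0).T))
    total = steps.sum()
    if total <= 0:
        raise ValueError("zero total path length")
    in_steps = steps[inside[:-1] & inside[1:]]
    return float(100.0 * in_steps.sum() / total)


def _dist_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(*(p - proj).T)


def thigmotaxis(traj: Trajectory, geometry: PoolGeometry) -> float:
    """Percentage of samples in the peripheral band along the pool wall."""
    r = np.hypot(traj.samples[:, 1], traj.samples[:, 2])
    band = r >= geometry.pool_radius - geometry.periphery_band_width
    return float(100.0 * band.mean())


def quadrant_occupancy(traj: Trajectory, geometry: PoolGeometry) -> dict[str, float]:
    """Percentage of samples per quadrant; the four values sum to 100."""
    labels = quadrant_labels(traj.samples[:, 1], traj.samples[:, 2])
    n = len(labels)
    return {q: float(100.0 * np.count_nonzero(labels == q) / n) for q in ("NE", "NW", "SW", "SE")}


def trial_metrics(
    traj: Trajectory,
    geometry: PoolGeometry,
    cutoff: float = 60.0,
) -> dict:
    """All seven variables for one trial, as a flat record.

    Reversal trials are scored against the reversed geometry's target
    quadrant and platform; the corridor uses the trial's own release point.
    """
    geom = geometry.reversed() if traj.phase == "reversal" else geometry
    latency, censored = latency_and_censoring(traj, cutoff=cutoff)
    distance, speed = path_length_and_speed(traj, latency=latency)
    occupancy = quadrant_occupancy(traj, geom)
    target = geom.target_quadrant
    return {
        "subject_id": traj.subject_id,
        "group": traj.group,
        "genotype": traj.genotype,
        "treatment": traj.treatment,
        "phase": traj.phase,
        "session": traj.session,
        "trial": traj.trial,
        "start_point": traj.start_point,
        "latency": latency,
        "censored": censored,
        "target_quadrant_time": occupancy[target],
        "thigmotaxis": thigmotaxis(traj, geom),
        "whishaw": whishaw_index(
            traj, corridor_half_width=geom.corridor_half_width
        ),
        "gallagher": gallagher_index(traj),
        "distance": distance,
        "speed": speed,
    }


def metrics_table(
    trajectories: list[Trajectory],
    geometry: PoolGeometry,
    cutoff: float = 60.0,
) -> pd.DataFrame:
    """Per-trial metric records for a collection of trajectories."""
    if not trajectories:
        raise ValueError("no trajectories given")
    return pd.DataFrame([trial_metrics(t, geometry, cutoff=cutoff) for t in trajectories])


def session_mean_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Average the trials of each subject-session into one record.

    Each of the seven variables is averaged arithmetically; the session is
    censored only if every trial was censored.
    """
    if records.empty:
        raise ValueError("no records to average")
    keys = ID_COLUMNS
    agg = {c: "mean" for c in METRIC_COLUMNS}
    agg["censored"] = "all"
    out = records.groupby(keys, sort=True, as_index=False).agg(agg)
    return out[keys + ["censored"] + METRIC_COLUMNS]


def cued_exclusion(cued_records: pd.DataFrame, threshold: float = 30.0) -> list[str]:
    """Subjects failing the visible-platform control: cued latency at or
    above the threshold (strict reading of "in less than 30 s")."""
    if not (cued_records["phase"] == "cued").all():
        raise ValueError("records are not all from the cued phase")
    bad = cued_records.loc[cued_records["latency"] >= threshold, "subject_id"]
    return sorted(bad.unique())


# ---------------------------------------------------------------------------
# Spatial summaries
# ---------------------------------------------------------------------------

@dataclass
class OccupancyGrid:
    """Dwell time (s) per square cell over the pool's bounding square."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    dwell: np.ndarray  # shape (nx, ny), seconds
    scope: str = ""

    @property
    def total_dwell(self) -> float:
        return float(self.dwell.sum())


def occupancy_heatmap(
    trajectories: list[Trajectory],
    geometry: PoolGeometry,
    bin_size: float = 5.0,
    scope: str = "",
) -> OccupancyGrid:
    """Accumulated dwell time per cell; total dwell equals the summed
    trajectory durations (each sample contributes one sampling interval)."""
    if not trajectories:
        raise ValueError("no trajectories given")
    R = geometry.pool_radius
    n = int(np.ceil(2 * R / bin_size))
    edges = -R + bin_size * np.arange(n + 1)
    dwell = np.zeros((n, n))
    for traj in trajectories:
        t = traj.samples[:, 0]
        dt = float(t[1] - t[0]) if len(t) > 1 else 0.1
        h, _, _ = np.histogram2d(
            traj.samples[:, 1], traj.samples[:, 2], bins=[edges, edges]
        )
        dwell += h * dt
    return OccupancyGrid(x_edges=edges, y_edges=edges, dwell=dwell, scope=scope)


@dataclass
class DensityGrid:
    """Gridded 2D Gaussian kernel density with equally spaced contour levels."""

    x: np.ndarray  # (grid_n,)
    y: np.ndarray  # (grid_n,)
    density: np.ndarray  # (grid_n, grid_n), indexed [ix, iy]
    levels: np.ndarray  # n_levels interior contour levels
    bandwidth: float


def density_grid(
    points: np.ndarray,
    grid_n: int = 100,
    bandwidth: float = 5.0,
    n_levels: int = 6,
    pad: float = 4.0,
) -> DensityGrid:
    """Bivariate Gaussian KDE on a square grid (defaults n = 100, h = 5,
    6 contour bins).  The kernel SD is ``bandwidth`` in both axes; the grid
    spans the data range padded by ``pad`` bandwidths so the density
    integrates to ≈ 1 over the grid."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    lo = pts.min(axis=0) - pad * bandwidth
    hi = pts.max(axis=0) + pad * bandwidth
    x = np.linspace(lo[0], hi[0], grid_n)
    y = np.linspace(lo[1], hi[1], grid_n)
    xx = (x[:, None] - pts[None, :, 0]) / bandwidth
    yy = (y[:, None] - pts[None, :, 1]) / bandwidth
    kx = np.exp(-0.5 * xx**2)
    ky = np.exp(-0.5 * yy**2)
    dens = kx @ ky.T / (len(pts) * 2.0 * np.pi * bandwidth**2)
    levels = np.linspace(0.0, dens.max(), n_levels + 1)[1:]
    return DensityGrid(x=x, y=y, density=dens, levels=levels, bandwidth=bandwidth)
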