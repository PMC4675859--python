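"""Synthetic swim-trajectory generator.

No raw tracking data are deposited for the cohort this analysis targets,
so the generator produces trajectories with the statistical structure the
downstream pipeline assumes: a discrete-time heading-persistence random
walk whose step direction mixes a goal-directed component (weight grows
across sessions — learning), a wall-following component (thigmotaxis) and
heading persistence, with Gaussian heading noise.  Trials terminate on
platform contact or are right-censored at the cutoff (600 samples at
10 Hz).  The 20 s the animal spends sitting on the platform after a
failed trial is not part of the recorded search path.

Randomness policy: one master seed; every (subject, phase, session,
trial) gets its own counter-based substream, so changing the cohort size
or schedule never perturbs other subjects' draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import CohortDesign, GroupBehavior
from .geometry import PoolGeometry

START_LABELS = ("N", "S", "E", "W")

PHASES = ("pretraining", "acquisition", "probe", "cued", "reversal")
_PHASE_CODE = {p: i for i, p in enumerate(PHASES)}

#: Wall-following direction = this mix of tangent and outward radial unit
#: vectors; the outward pull keeps a wall-following animal pressed to the rim.
_WALL_TANGENT_SHARE = 0.85


@dataclass
class Trajectory:
    """One trial's timestamped path.

    ``samples`` is an (n, 3) float array of (t, x, y) rows at a fixed
    0.1 s step starting at t = 0.  ``goal`` is the platform center used
    for goal-directed metrics; on probe trials the platform is absent
    (``platform_present`` False) but ``goal`` still records its former
    position.  ``censored`` is True iff the platform was never contacted
    before the cutoff (probe trials are always censored by convention).
    """

    subject_id: str
    group: str
    genotype: str
    treatment: str
    phase: str
    session: int
    trial: int
    start_point: str
    samples: np.ndarray
    censored: bool
    goal: tuple[float, float]
    platform_present: bool = True

    @property
    def duration(self) -> float:
        return float(self.samples[-1, 0])


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


def simulate_trial(
    geometry: PoolGeometry,
    behavior: GroupBehavior,
    session: int,
    start: str,
    rng: np.random.Generator,
    *,
    phase: str = "acquisition",
    trial: int = 1,
    cutoff: float = 60.0,
    dt: float = 0.1,
    goal: tuple[float, float] | None = None,
    platform_present: bool = True,
    goal_bias: float | None = None,
    subject_id: str = "subject",
    group: str = "group",
    genotype: str = "WT",
    treatment: str = "NT",
) -> Trajectory:
    """Simulate a single trial.

    ``start`` is a compass release label (N/S/E/W); ``goal`` defaults to
    the geometry's platform center; ``goal_bias`` overrides the learned
    session-dependent bias (used for cued/pretraining trials where the
    platform is visible).  The trial ends at first platform contact, or
    after exactly ``cutoff × sample_rate`` samples with ``censored`` True.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    x, y = geometry.start_position(start)
    gx, gy = geometry.platform_center if goal is None else goal
    g = behavior.goal_bias(session) if goal_bias is None else float(goal_bias)
    if not 0.0 <= g <= 1.0:
        raise ValueError("goal_bias must lie in [0, 1]")
    speed = max(1.0, rng.normal(behavior.base_speed, behavior.speed_sd))
    if speed <= 0:
        raise ValueError("non-positive speed")
    tw = behavior.thigmotaxis_weight
    w_wall = tw * (1.0 - g)
    w_prev = (1.0 - tw) * (1.0 - g)
    noise = behavior.heading_noise_sd
    R = geometry.pool_radius
    pr = geometry.platform_radius
    n_max = int(round(cutoff / dt))
    step = speed * dt

    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    hx, hy = math.cos(theta0), math.sin(theta0)

    ts = [0.0]
    xs = [x]
    ys = [y]
    censored = True
    for i in range(1, n_max):
        dxg, dyg = gx - x, gy - y
        dg = math.hypot(dxg, dyg)
        if dg > 1e-12:
            ugx, ugy = dxg / dg, dyg / dg
        else:
            ugx, ugy = hx, hy
        r = math.hypot(x, y)
        if r > 1e-9:
            ox, oy = x / r, y / r
            twx = -oy * _WALL_TANGENT_SHARE + ox * (1.0 - _WALL_TANGENT_SHARE)
            twy = ox * _WALL_TANGENT_SHARE + oy * (1.0 - _WALL_TANGENT_SHARE)
            nw = math.hypot(twx, twy)
            uwx, uwy = twx / nw, twy / nw
        else:
            uwx, uwy = 1.0, 0.0
        vx = g * ugx + w_wall * uwx + w_prev * hx
        vy = g * ugy + w_wall * uwy + w_prev * hy
        nv = math.hypot(vx, vy)
        if nv < 1e-12:
            vx, vy = hx, hy
            nv = 1.0
        vx, vy = vx / nv, vy / nv
        if noise > 0.0:
            eps = rng.normal(0.0, noise)
            c, s = math.cos(eps), math.sin(eps)
            vx, vy = c * vx - s * vy, s * vx + c * vy
        x += step * vx
        y += step * vy
        rr = math.hypot(x, y)
        if rr > R:
            x *= R / rr
            y *= R / rr
        hx, hy = vx, vy
        ts.append(i * dt)
        xs.append(x)
        ys.append(y)
        if platform_present and math.hypot(x - gx, y - gy) <= pr:
            censored = False
            break
    samples = np.column_stack([ts, xs, ys])
    return Trajectory(
        subject_id=subject_id,
        group=group,
        genotype=genotype,
        treatment=treatment,
        phase=phase,
        session=session,
        trial=trial,
        start_point=start,
        samples=samples,
        censored=censored,
        goal=(gx, gy),
        platform_present=platform_present,
    )


def _session_starts(rng: np.random.Generator, n_trials: int) -> list[str]:
    """Release points within a session: permutations of N/S/E/W, repeated
    as needed for longer sessions."""
    starts: list[str] = []
    while len(starts) < n_trials:
        starts.extend(rng.permutation(START_LABELS))
    return starts[:n_trials]


def simulate_cohort(design: CohortDesign, geometry: PoolGeometry | None = None) -> list[Trajectory]:
    """Simulate the full protocol for every subject in the design.

    Schedule per subject: optional pretraining trial (visible platform at
    the pool center), ``n_acquisition_sessions × trials_per_session``
    acquisition trials, optional probe (platform removed, fixed 60 s) and
    cued trials, then ``n_reversal_sessions × trials_per_session``
    reversal trials with the platform point-reflected through the pool
    center.
    """
    geometry = geometry or PoolGeometry()
    rev_geometry = geometry.reversed()
    out: list[Trajectory] = []
    for gi, grp in enumerate(design.groups):
        for si in range(grp.n_subjects):
            sid = f"{grp.label}_{si + 1:02d}"
            srng = _substream(design.seed, gi, si, 9)
            behavior = replace(
                grp.behavior,
                learning_rate=max(
                    0.0,
                    grp.behavior.learning_rate
                    + srng.normal(0.0, grp.behavior.subject_rate_sd),
                ),
                base_speed=max(
                    5.0,
                    grp.behavior.base_speed
                    + srng.normal(0.0, grp.behavior.subject_speed_sd),
                ),
            )
            common = dict(
                subject_id=sid,
                group=grp.label,
                genotype=grp.genotype,
                treatment=grp.treatment,
                cutoff=design.trial_cutoff,
                dt=design.dt,
            )

            def trial_rng(phase: str, session: int, trial: int) -> np.random.Generator:
                return _substream(design.seed, gi, si, _PHASE_CODE[phase], session, trial)

            if design.include_pretraining:
                rng = trial_rng("pretraining", 0, 1)
                start = str(rng.choice(START_LABELS))
                out.append(
                    simulate_trial(
                        geometry, behavior, 0, start, rng,
                        phase="pretraining", trial=1, goal=(0.0, 0.0),
                        goal_bias=behavior.cue_bias, **common,
                    )
                )
            for sess in range(1, design.n_acquisition_sessions + 1):
                starts = _session_starts(
                    trial_rng("acquisition", sess, 0), design.trials_per_session
                )
                for tr, start in enumerate(starts, start=1):
                    rng = trial_rng("acquisition", sess, tr)
                    out.append(
                        simulate_trial(
                            geometry, behavior, sess, start, rng,
                            phase="acquisition", trial=tr, **common,
                        )
                    )
            if design.include_probe:
                rng = trial_rng("probe", 1, 1)
                start = str(rng.choice(START_LABELS))
                out.append(
                    simulate_trial(
                        geometry, behavior, design.n_acquisition_sessions, start, rng,
                        phase="probe", trial=1, platform_present=False, **common,
                    )
                )
            if design.include_cued:
                rng = trial_rng("cued", 1, 1)
                start = str(rng.choice(START_LABELS))
                out.append(
                    simulate_trial(
                        geometry, behavior, 1, start, rng,
                        phase="cued", trial=1, goal_bias=behavior.cue_bias, **common,
                    )
                )
            for sess in range(1, design.n_reversal_sessions + 1):
                starts = _session_starts(
                    trial_rng("reversal", sess, 0), design.trials_per_session
                )
                for tr, start in enumerate(starts, start=1):
                    rng = trial_rng("reversal", sess, tr)
                    out.append(
                        simulate_trial(
                            rev_geometry, behavior, sess, start, rng,
                            phase="reversal", trial=tr, **common,
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# Fast path: draw per-subject-session metric records directly, bypassing
# trajectory simulation.  Used for statistical calibration where only the
# joint distribution of the seven metrics matters.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """Group×session mean vectors plus a shared covariance for the seven
    metrics (column order :data:`watermaze.metrics.METRIC_COLUMNS`)."""

    means: dict  # (group label, session) -> length-7 array
    cov: np.ndarray

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (7, 7):
            raise ValueError("cov must be 7×7")
        if not np.allclose(cov, cov.T):
            raise ValueError("cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-8:
            raise ValueError("cov must be positive semi-definite")
        object.__setattr__(self, "cov", cov)

    @classmethod
    def null(cls, design: CohortDesign, cov: np.ndarray | None = None) -> "EffectSpec":
        """All groups share the same session-dependent means (no group
        effect) — the exchangeable-subjects null used for calibration."""
        if cov is None:
            cov = default_metric_covariance()
        means = {}
        for s in range(1, design.n_acquisition_sessions + 1):
            mu = _default_session_means(s)
            for label in design.group_labels:
                means[(label, s)] = mu
        return cls(means=means, cov=cov)

    def shifted(self, group: str, delta: np.ndarray) -> "EffectSpec":
        """Copy with ``delta`` added to every session mean of ``group``."""
        delta = np.asarray(delta, dtype=float)
        means = {
            key: (mu + delta if key[0] == group else mu) for key, mu in self.means.items()
        }
        return EffectSpec(means=means, cov=self.cov)


def _default_session_means(session: int) -> np.ndarray:
    # order: latency, target_quadrant_time, thigmotaxis, whishaw, gallagher,
    # distance, speed — a moderate learning trend shared by all groups
    s = session - 1
    return np.array(
        [50.0 - 5.0 * s, 25.0 + 3.0 * s, 40.0 - 4.0 * s, 20.0 + 5.0 * s,
         45.0 - 4.0 * s, 900.0 - 80.0 * s, 18.0]
    )


def default_metric_covariance() -> np.ndarray:
    """One-factor correlation structure among the learning-related metrics
    (speed nearly independent), scaled by realistic per-metric SDs."""
    sds = np.array([12.0, 12.0, 12.0, 12.0, 10.0, 250.0, 2.5])
    a = np.array([0.7, -0.6, 0.6, -0.6, 0.7, 0.6, 0.1])
    corr = np.outer(a, a)
    np.fill_diagonal(corr, 1.0)
    return corr * np.outer(sds, sds)


#: truncation bounds per metric column (latency upper bound = cutoff)
_METRIC_LO = np.array([0.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.5])
_METRIC_HI = np.array([60.0, 100.0, 100.0, 100.0, 170.0, np.inf, np.inf])


def generate_metric_table(
    design: CohortDesign,
    effect_spec: EffectSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw one session-mean metric record per subject and session.

    Records are multivariate normal around the group×session means,
    truncated to each metric's valid range; latencies at the cutoff are
    flagged censored.  Substreams are per subject, so adding groups or
    subjects leaves existing subjects' records unchanged.
    """
    from .metrics import METRIC_COLUMNS

    if effect_spec is None:
        effect_spec = EffectSpec.null(design)
    seed = design.seed if seed is None else seed
    hi = _METRIC_HI.copy()
    hi[0] = design.trial_cutoff
    for (label, s), mu in effect_spec.means.items():
        mu = np.asarray(mu, dtype=float)
        if not (0.0 < mu[0] <= design.trial_cutoff):
            raise ValueError(f"mean latency out of range for {(label, s)}")
        if np.any(mu[1:4] < 0.0) or np.any(mu[1:4] > 100.0):
            raise ValueError(f"mean percentage out of range for {(label, s)}")
    # PSD square root via eigendecomposition (tolerates singular covariances)
    w, V = np.linalg.eigh(effect_spec.cov)
    chol = V * np.sqrt(np.clip(w, 0.0, None))
    sessions = range(1, design.n_acquisition_sessions + 1)
    rows = []
    for gi, grp in enumerate(design.groups):
        for si in range(grp.n_subjects):
            rng = _substream(seed, gi, si, 5)
            z = rng.standard_normal((design.n_acquisition_sessions, 7))
            for s in sessions:
                mu = np.asarray(effect_spec.means[(grp.label, s)], dtype=float)
                vals = np.clip(mu + z[s - 1] @ chol.T, _METRIC_LO, hi)
                rows.append(
                    {
                        "subject_id": f"{grp.label}_{si + 1:02d}",
                        "group": grp.label,
                        "genotype": grp.genotype,
                        "treatment": grp.treatment,
                        "phase": "acquisition",
                        "session": s,
                        "censored": bool(vals[0] >= design.trial_cutoff),
                        **dict(zip(METRIC_COLUMNS, vals)),
                    }
                )
    return pd.DataFrame(rows)
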