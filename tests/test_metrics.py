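"""Behavioral metrics: closed-form cases, brute-force geometry oracles,
rigid-motion invariances, aggregation rules, spatial grids."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from watermaze.geometry import PoolGeometry
from watermaze.metrics import (
    cued_exclusion,
    density_grid,
    gallagher_index,
    latency_and_censoring,
    occupancy_heatmap,
    path_length_and_speed,
    quadrant_occupancy,
    session_mean_metrics,
    thigmotaxis,
    whishaw_index,
)
from watermaze.simulate import Trajectory


def make_traj(xy, phase="acquisition", goal=(40.0, 40.0), platform_present=True, dt=0.1):
    xy = np.asarray(xy, dtype=float)
    t = dt * np.arange(len(xy))
    samples = np.column_stack([t, xy])
    return Trajectory(
        subject_id="s", group="WT", genotype="WT", treatment="NT",
        phase=phase, session=1, trial=1, start_point="N",
        samples=samples, censored=False, goal=goal,
        platform_present=platform_present,
    )


class TestLatency:
    def test_contact_time_from_sample_index(self):
        # approach the goal along a line; contact at the final sample
        xy = np.column_stack([np.linspace(0, 40, 124), np.linspace(-80, 40, 124)])
        traj = make_traj(xy, goal=(40.0, 40.0))
        lat, cens = latency_and_censoring(traj)
        assert not cens
        assert lat == pytest.approx(0.1 * np.flatnonzero(
            np.hypot(xy[:, 0] - 40, xy[:, 1] - 40) <= 6.0)[0])

    def test_cutoff_when_never_on_platform(self):
        xy = np.tile([(-50.0, -50.0)], (600, 1))
        lat, cens = latency_and_censoring(make_traj(xy, goal=(40.0, 40.0)))
        assert (lat, cens) == (60.0, True)

    def test_immediate_contact(self):
        xy = np.array([[0.0, -80.0], [40.0, 40.0]])
        lat, cens = latency_and_censoring(make_traj(xy))
        assert (lat, cens) == (0.1, False)

    def test_empty_trajectory_rejected(self):
        traj = make_traj(np.array([[0.0, 0.0]]))
        traj.samples = traj.samples[:0]
        with pytest.raises(ValueError):
            latency_and_censoring(traj)


class TestPathLength:
    def test_uniform_straight_motion(self):
        xy = np.column_stack([np.linspace(0, 100, 101), np.zeros(101)])
        d, v = path_length_and_speed(make_traj(xy, goal=(200.0, 0.0)), latency=10.0)
        assert d == pytest.approx(100.0)
        assert v == pytest.approx(10.0)

    def test_stationary_animal(self):
        xy = np.tile([(5.0, 5.0)], (11, 1))
        d, v = path_length_and_speed(make_traj(xy), latency=1.0)
        assert (d, v) == (0.0, 0.0)

    def test_circle_circumference_oracle(self):
        theta = np.linspace(0.0, 2 * np.pi, 361)
        xy = 50.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        d, _ = path_length_and_speed(make_traj(xy), latency=36.0)
        assert d == pytest.approx(2 * np.pi * 50.0, rel=1e-4)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            path_length_and_speed(make_traj(np.array([[0.0, 0.0]])))


def _gallagher_oracle(distances):
    """Independent 1-s block-averaging implementation."""
    blocks = []
    i = 0
    while i < len(distances):
        blocks.append(float(np.mean(distances[i : i + 10])))
        i += 10
    return float(np.mean(blocks))


class TestGallagher:
    def test_constant_distance(self):
        xy = np.tile([(10.0, 40.0)], (57, 1))
        assert gallagher_index(make_traj(xy, goal=(40.0, 40.0))) == pytest.approx(30.0, abs=1e-9)

    def test_circle_centered_on_goal(self):
        theta = np.linspace(0, 4 * np.pi, 83)
        xy = np.column_stack([40 + 25 * np.cos(theta), 40 + 25 * np.sin(theta)])
        assert gallagher_index(make_traj(xy, goal=(40.0, 40.0))) == pytest.approx(25.0, abs=1e-9)

    def test_linear_approach_against_block_oracle(self):
        # 50 cm -> 0 cm at constant radial speed over 5 s (51 samples)
        d = np.linspace(50.0, 0.0, 51)
        xy = np.column_stack([40.0 - d, np.full(51, 40.0)])
        expected = _gallagher_oracle(d)
        assert gallagher_index(make_traj(xy, goal=(40.0, 40.0))) == pytest.approx(expected, abs=1e-9)

    def test_rotation_invariance(self, rng):
        xy = rng.uniform(-60, 60, size=(123, 2))
        goal = np.array([30.0, 20.0])
        a = gallagher_index(make_traj(xy, goal=tuple(goal)))
        phi = 1.234
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        b = gallagher_index(make_traj(xy @ rot.T, goal=tuple(rot @ goal)))
        assert a == pytest.approx(b, abs=1e-9)


class TestWhishaw:
    def test_straight_path_is_100(self):
        xy = np.column_stack([np.linspace(0, 40, 50), np.linspace(-80, 40, 50)])
        w = whishaw_index(make_traj(xy), start=(0.0, -80.0), goal=(40.0, 40.0))
        assert w == pytest.approx(100.0, abs=1e-9)

    def test_disjoint_path_is_0(self):
        xy = np.column_stack([np.linspace(-60, -60, 30), np.linspace(-40, 40, 30)])
        w = whishaw_index(make_traj(xy), start=(0.0, -80.0), goal=(40.0, 40.0),
                          corridor_half_width=10.0)
        assert w == 0.0

    def test_two_leg_40_60_split(self):
        """40 cm along the corridor axis then 60 cm straight out of it."""
        leg1 = np.column_stack([np.linspace(0, 40, 5), np.zeros(5)])
        leg2 = np.column_stack([np.full(6, 40.0), np.linspace(12, 60, 6)])
        xy = np.vstack([leg1, leg2])
        w = whishaw_index(make_traj(xy), start=(0.0, 0.0), goal=(100.0, 0.0),
                          corridor_half_width=10.0)
        # the 12 cm hop from (40,0) to (40,12) has one endpoint inside, so
        # only the first 40 cm count; total path = 40 + 60 = 100
        assert w == pytest.approx(40.0, abs=1e-9)

    def test_against_shapely_capsule_oracle(self, rng):
        from shapely.geometry import LineString, Point

        start, goal, width = (0.0, -70.0), (40.0, 40.0), 11.0
        corridor = LineString([start, goal]).buffer(width)
        xy = rng.uniform(-80, 80, size=(60, 2))
        inside = np.array([corridor.covers(Point(p)) for p in xy])
        steps = np.hypot(*np.diff(xy, axis=0).T)
        expected = 100.0 * steps[inside[:-1] & inside[1:]].sum() / steps.sum()
        got = whishaw_index(make_traj(xy), start=start, goal=goal, corridor_half_width=width)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_rigid_motion_invariance(self, rng):
        xy = rng.uniform(-70, 70, size=(80, 2))
        start, goal = np.array([0.0, -70.0]), np.array([40.0, 40.0])
        a = whishaw_index(make_traj(xy), start=tuple(start), goal=tuple(goal))
        phi, shift = 0.7, np.array([13.0, -8.0])
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        b = whishaw_index(
            make_traj(xy @ rot.T + shift),
            start=tuple(rot @ start + shift), goal=tuple(rot @ goal + shift),
        )
        assert a == pytest.approx(b, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        xy = np.tile([(1.0, 1.0)], (5, 1))
        with pytest.raises(ValueError, match="coincide"):
            whishaw_index(make_traj(xy), start=(2.0, 2.0), goal=(2.0, 2.0))
        with pytest.raises(ValueError, match="path length"):
            whishaw_index(make_traj(xy), start=(0.0, 0.0), goal=(9.0, 0.0))


class TestThigmotaxisQuadrants:
    def test_wall_and_center_limits(self, geometry):
        at_wall = np.tile([(0.0, 84.9)], (20, 1))
        at_center = np.tile([(0.0, 0.0)], (20, 1))
        assert thigmotaxis(make_traj(at_wall), geometry) == 100.0
        assert thigmotaxis(make_traj(at_center), geometry) == 0.0

    def test_half_in_band(self, geometry):
        xy = np.array([(0.0, 80.0), (0.0, 0.0)] * 25)
        assert thigmotaxis(make_traj(xy), geometry) == pytest.approx(50.0)

    def test_quadrant_confinement_and_symmetry(self, geometry):
        ne = np.tile([(30.0, 30.0)], (9, 1))
        occ = quadrant_occupancy(make_traj(ne), geometry)
        assert occ == {"NE": 100.0, "NW": 0.0, "SW": 0.0, "SE": 0.0}
        theta = (np.arange(8) + 0.5) * np.pi / 4
        ring = 40 * np.column_stack([np.cos(theta), np.sin(theta)])
        occ = quadrant_occupancy(make_traj(ring), geometry)
        assert all(v == 25.0 for v in occ.values())

    def test_axis_points_get_counterclockwise_quadrant(self, geometry):
        axis_pts = np.array([(50.0, 0.0), (0.0, 50.0), (-50.0, 0.0), (0.0, -50.0)])
        occ = quadrant_occupancy(make_traj(axis_pts), geometry)
        assert all(v == 25.0 for v in occ.values())

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_quadrant_shares_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 300)
        r = 85 * np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(0, 2 * np.pi, n)
        xy = np.column_stack([r * np.cos(th), r * np.sin(th)])
        occ = quadrant_occupancy(make_traj(xy), PoolGeometry())
        assert sum(occ.values()) == pytest.approx(100.0, abs=1e-9)


def _records(rows):
    base = dict(subject_id="s1", group="WT", genotype="WT", treatment="NT",
                phase="acquisition", session=1)
    return pd.DataFrame([{**base, **r} for r in rows])


class TestAggregation:
    def test_session_mean_is_arithmetic(self):
        rows = [
            dict(trial=k + 1, latency=v, censored=(v == 60.0),
                 target_quadrant_time=10.0, thigmotaxis=20.0, whishaw=30.0,
                 gallagher=40.0, distance=500.0, speed=15.0)
            for k, v in enumerate([10.0, 20.0, 30.0, 60.0])
        ]
        out = session_mean_metrics(_records(rows))
        assert len(out) == 1
        assert out.loc[0, "latency"] == pytest.approx(30.0)
        assert not out.loc[0, "censored"]  # not all trials censored

    def test_idempotent_on_identical_trials(self):
        rows = [dict(trial=k + 1, latency=12.0, censored=False,
                     target_quadrant_time=55.0, thigmotaxis=5.0, whishaw=80.0,
                     gallagher=25.0, distance=200.0, speed=17.0) for k in range(4)]
        out = session_mean_metrics(_records(rows))
        assert out.loc[0, "whishaw"] == 80.0

    def test_commutes_with_trial_order(self):
        rows = [dict(trial=k + 1, latency=float(v), censored=False,
                     target_quadrant_time=1.0 * v, thigmotaxis=2.0, whishaw=3.0,
                     gallagher=4.0, distance=5.0, speed=6.0)
                for k, v in enumerate([7, 11, 13, 17])]
        a = session_mean_metrics(_records(rows))
        b = session_mean_metrics(_records(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_all_censored_flags_session(self):
        rows = [dict(trial=k + 1, latency=60.0, censored=True,
                     target_quadrant_time=10.0, thigmotaxis=50.0, whishaw=5.0,
                     gallagher=50.0, distance=1000.0, speed=17.0) for k in range(4)]
        assert session_mean_metrics(_records(rows)).loc[0, "censored"]

    @pytest.mark.parametrize(
        "latency,excluded",
        [(29.9, False), (30.0, True), (60.0, True)],
    )
    def test_cued_exclusion_boundary(self, latency, excluded):
        df = _records([dict(trial=1, latency=latency, censored=latency >= 60,
                            target_quadrant_time=0.0, thigmotaxis=0.0,
                            whishaw=0.0, gallagher=0.0, distance=0.0, speed=0.0)])
        df["phase"] = "cued"
        out = cued_exclusion(df)
        assert (out == ["s1"]) == excluded

    def test_cued_exclusion_requires_cued_phase(self):
        df = _records([dict(trial=1, latency=10.0, censored=False,
                            target_quadrant_time=0, thigmotaxis=0, whishaw=0,
                            gallagher=0, distance=0, speed=0)])
        with pytest.raises(ValueError):
            cued_exclusion(df)


class TestGrids:
    def test_heatmap_conserves_and_doubles(self, geometry):
        xy = np.tile([(10.0, 10.0)], (30, 1))
        t1 = make_traj(xy)
        grid1 = occupancy_heatmap([t1], geometry)
        assert grid1.total_dwell == pytest.approx(30 * 0.1)
        assert np.count_nonzero(grid1.dwell) == 1
        grid2 = occupancy_heatmap([t1, t1], geometry)
        np.testing.assert_allclose(grid2.dwell, 2 * grid1.dwell)

    def test_density_grid_integrates_to_one(self, rng):
        pts = rng.normal(0.0, 1.0, size=(400, 2))
        g = density_grid(pts, grid_n=100, bandwidth=5.0, n_levels=6)
        integral = np.trapezoid(np.trapezoid(g.density, g.y, axis=1), g.x)
        assert 0.98 <= integral <= 1.0 + 1e-6
        assert len(g.levels) == 6
        dl = np.diff(g.levels)
        np.testing.assert_allclose(dl, dl[0])

    def test_empty_inputs_rejected(self, geometry):
        with pytest.raises(ValueError):
            occupancy_heatmap([], geometry)
        with pytest.raises(ValueError):
            density_grid(np.empty((0, 2)))
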