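import dataclasses

import numpy as np
import pytest

from consink import goalstats, prep, synth
from consink.prep import PosedSpikes
from consink.synth import Subtrial, TaskEvents, Tracking


@pytest.fixture(scope="module")
def goal_population(maze):
    """Goal-clustered ConSink population with forward preferred directions."""
    goal_xy = maze.centers[maze.goal]
    rng = np.random.default_rng(50)
    cells = synth.make_cells(rng, maze, 12, "consink", sink_center=goal_xy,
                             sink_sd=8.0, mu_rd_sd=8.0, kappa_rd=(2.5, 2.5),
                             base_rate=(2, 3), field_sigma=None)
    ses = synth.generate_session(cells, seed=51, maze=maze, n_trials=8)
    posed = [
        prep.interpolate_pose(ses.spikes[c.cell_id], ses.tracking, c.cell_id,
                              maze)
        for c in cells
    ]
    return ses, cells, posed, goal_xy


class TestFantail:
    def test_zscore_identity_and_peak(self, goal_population):
        ses, _, posed, goal_xy = goal_population
        ft = goalstats.fantail(posed, ses.tracking, goal_xy)
        ok = np.isfinite(ft.z)
        assert np.mean(ft.z[ok]) == pytest.approx(0.0, abs=1e-12)
        assert np.std(ft.z[ok]) == pytest.approx(1.0, abs=1e-12)
        assert ft.bin_centers[np.nanargmax(ft.rate)] == 0.0

    def test_rotation_equivariance_about_goal(self, goal_population):
        ses, _, posed, goal_xy = goal_population
        base = goalstats.fantail(posed, ses.tracking, goal_xy)
        th = np.deg2rad(40.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

        def rot_tracking(tr):
            return Tracking(
                tr.t, (tr.head_xy - goal_xy) @ R.T + goal_xy,
                (tr.head_dir + 40.0) % 360.0,
                (tr.torso_xy - goal_xy) @ R.T + goal_xy, tr.platform,
            )

        def rot_spikes(sp):
            xy = (np.stack([sp.x, sp.y], 1) - goal_xy) @ R.T + goal_xy
            return PosedSpikes(sp.cell_id, sp.t, xy[:, 0], xy[:, 1],
                               (sp.head_dir + 40.0) % 360.0, sp.platform)

        rot = goalstats.fantail(
            [rot_spikes(s) for s in posed], rot_tracking(ses.tracking), goal_xy
        )
        assert np.allclose(rot.rate, base.rate, equal_nan=True)

    def test_direction_blind_population_is_flat(self, maze):
        rng = np.random.default_rng(52)
        cells = synth.make_cells(rng, maze, 10, "uniform", base_rate=(2, 3),
                                 field_sigma=None)
        ses = synth.generate_session(cells, seed=53, maze=maze, n_trials=8)
        posed = [
            prep.interpolate_pose(ses.spikes[c.cell_id], ses.tracking,
                                  c.cell_id, maze)
            for c in cells
        ]
        ft = goalstats.fantail(posed, ses.tracking, maze.centers[maze.goal])
        ok = np.isfinite(ft.rate)
        # rates vary by only a few percent around the mean; no goalward peak
        assert np.ptp(ft.rate[ok]) / np.mean(ft.rate[ok]) < 0.25
        assert np.all(np.abs(ft.z[ok]) < 2.5)


class TestWaitPeriodRates:
    def test_full_cone_recovers_overall_rate(self, goal_population):
        ses, cells, posed, goal_xy = goal_population
        sp = posed[0]
        w = ses.task.subtrials[2].wait1
        full = goalstats.goalward_rate(sp, ses.tracking, w, goal_xy, tol=180.0)
        m = (sp.t >= w[0]) & (sp.t < w[1])
        occ = np.sum((ses.tracking.t >= w[0]) & (ses.tracking.t < w[1]))
        assert full == pytest.approx(m.sum() / (occ * ses.tracking.dt))

    def test_goal_tuned_cell_fires_goalward(self, goal_population):
        ses, cells, posed, goal_xy = goal_population
        windows = ses.task.wait_windows(1)
        for sp in posed[:4]:
            goalward = goalstats.goalward_rate(sp, ses.tracking, windows,
                                               goal_xy, tol=15.0)
            overall = goalstats.goalward_rate(sp, ses.tracking, windows,
                                              goal_xy, tol=180.0)
            assert goalward > overall

    def test_label_swap_flips_median_difference(self, goal_population, maze):
        ses, cells, posed, goal_xy = goal_population
        cc = [
            {"spikes": sp, "sink": c.sink_xy, "preferred_rd": c.mu_rd}
            for c, sp in zip(cells, posed)
        ]
        res = goalstats.compare_correct_error(cc, ses.task, ses.tracking,
                                              goal_xy, min_trials=1)
        flipped_task = TaskEvents(
            [
                dataclasses.replace(
                    s, correct=None if s.correct is None else not s.correct
                )
                for s in ses.task.subtrials
            ],
            goal=ses.task.goal,
        )
        res_f = goalstats.compare_correct_error(cc, flipped_task, ses.tracking,
                                                goal_xy, min_trials=1)
        a = res["wait1"]["median_goalward_diff"]
        b = res_f["wait1"]["median_goalward_diff"]
        assert a == pytest.approx(-b, abs=1e-9)

    def test_insufficient_error_trials_reported(self, goal_population):
        ses, cells, posed, goal_xy = goal_population
        cc = [{"spikes": posed[0], "sink": cells[0].sink_xy,
               "preferred_rd": cells[0].mu_rd}]
        res = goalstats.compare_correct_error(cc, ses.task, ses.tracking,
                                              goal_xy, min_trials=10_000)
        assert res["wait1"]["computable"] is False


class TestGoalShiftDistances:
    def test_degenerate_sinks_at_goal1(self):
        g1, g2 = np.array([0.0, 0.0]), np.array([100.0, 0.0])
        s1 = np.tile(g1, (20, 1)) + 1e-6
        s2 = np.tile(g2, (20, 1)) + 1e-6
        res = goalstats.sink_goal_distances(s1, s2, g1, g2, paired=(s1, s2))
        assert res["p_epoch1"] < 1e-6
        assert res["p_epoch2"] < 1e-6
        assert res["fraction_moved_toward_goal2"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            goalstats.sink_goal_distances(np.zeros((0, 2)), np.zeros((3, 2)),
                                          (0, 0), (1, 1))


class TestRemapping:
    def test_stable_population_beats_remapped(self, maze):
        rng = np.random.default_rng(29)
        cells = synth.make_cells(rng, maze, 8, "place_only", prefix="stable",
                                 base_rate=(2, 3))
        task = synth.generate_task(maze, 8, seed=201)
        trT = synth.generate_trajectory(task, maze, seed=202)
        trF = synth.generate_forage_tracking(maze, 400.0, seed=203)
        spT = [
            prep.interpolate_pose(synth.generate_spikes(c, trT, 300 + i), trT,
                                  c.cell_id, maze)
            for i, c in enumerate(cells)
        ]
        spF = [
            prep.interpolate_pose(synth.generate_spikes(c, trF, 400 + i), trF,
                                  c.cell_id, maze)
            for i, c in enumerate(cells)
        ]
        remapped_cells = [
            dataclasses.replace(
                c, field_center=tuple(maze.centers[rng.integers(61)])
            )
            for c in cells
        ]
        spF_re = [
            prep.interpolate_pose(synth.generate_spikes(c, trF, 500 + i), trF,
                                  c.cell_id, maze)
            for i, c in enumerate(remapped_cells)
        ]
        stable = goalstats.remapping(spT, spF, trT, trF)
        remap = goalstats.remapping(spT, spF_re, trT, trF)
        assert np.nanmedian(stable.cell_corr) > np.nanmedian(remap.cell_corr)
        assert np.nanmedian(stable.pv_corr) > np.nanmedian(remap.pv_corr)
        # identical maps correlate perfectly
        self_rep = goalstats.remapping(spT, spT, trT, trT)
        assert np.allclose(self_rep.cell_corr, 1.0)


class TestPlaceFieldCenterAndBehaviour:
    def test_center_of_mass_cases(self):
        rm = prep.RateMap(
            x_edges=np.arange(5.0), y_edges=np.arange(4.0),
            occupancy=np.ones((3, 4)), counts=np.zeros((3, 4)),
            rate=np.zeros((3, 4)),
        )
        rm.rate[1, 2] = 5.0
        assert goalstats.place_field_center(rm) == (2.5, 1.5)
        rm.rate[:] = 0.0
        rm.rate[0, 0] = 3.0
        rm.rate[2, 0] = 3.0
        assert goalstats.place_field_center(rm)[1] == pytest.approx(1.5)
        rm.rate[:] = 0.0
        with pytest.raises(ValueError):
            goalstats.place_field_center(rm)

    def _task(self, outcomes):
        subs = [
            Subtrial(0, i, 0, (1, 2), 1, c, 0.0, 1.0, 2.0, (0, 4), (5, 9))
            for i, c in enumerate(outcomes)
        ]
        return TaskEvents(subs, goal=45)

    def test_binomial_closed_forms(self):
        res = goalstats.behavioural_score(self._task([True] * 10))
        assert res["binomial_p"] == pytest.approx(0.5**10)
        res5 = goalstats.behavioural_score(self._task([True] * 5 + [False] * 5))
        assert res5["binomial_p"] > 0.5
        # equidistant (unscored) choices are excluded
        res_u = goalstats.behavioural_score(self._task([True] * 10 + [None] * 7))
        assert res_u["n_scored"] == 10
        with pytest.raises(ValueError):
            goalstats.behavioural_score(self._task([None, None]))
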