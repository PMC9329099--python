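import numpy as np
import pingouin as pg
import pytest

from consink import prep, sinks, synth
from consink._circ import angular_difference
from consink.prep import PosedSpikes
from consink.synth import Tracking


def _single_platform_tracking(n=2000, hd=None, pos=(0.0, 0.0)):
    """Stationary animal on one 'platform' with prescribed headings."""
    t = np.arange(n) / 25.0
    if hd is None:
        hd = (np.arange(n) * 360.0 / n) % 360.0
    xy = np.tile(np.asarray(pos, float), (n, 1))
    return Tracking(t, xy, np.asarray(hd, float), xy.copy(), np.zeros(n, int))


class TestCorrectedTuning:
    def test_point_mass_toward_sink(self):
        tr = _single_platform_tracking()
        sink = (30.0, 0.0)
        m = np.abs(angular_difference(tr.head_dir, 0.0)) < 2.0
        sp = PosedSpikes("c", tr.t[m], tr.head_xy[m, 0], tr.head_xy[m, 1],
                         tr.head_dir[m], tr.platform[m])
        tun = sinks.corrected_tuning(sp, tr, sink)
        assert abs(tun.mean_dir) < 8.0
        assert tun.mrl > 0.95

    def test_uniform_occupancy_gives_raw_histogram(self):
        tr = _single_platform_tracking(n=2400)  # exactly uniform headings
        rng = np.random.default_rng(0)
        pick = rng.random(tr.n_frames) < 0.3
        sp = PosedSpikes("c", tr.t[pick], tr.head_xy[pick, 0],
                         tr.head_xy[pick, 1], tr.head_dir[pick],
                         tr.platform[pick])
        tun = sinks.corrected_tuning(sp, tr, (40.0, 10.0))
        ratio = tun.corrected[tun.defined] / np.maximum(
            tun.spike_hist[tun.defined], 1e-12
        )
        ratio = ratio[tun.spike_hist[tun.defined] > 0]
        assert np.allclose(ratio, ratio[0])

    def test_weighted_stats_match_pingouin(self):
        """Internal weighted circular statistics vs the pingouin oracle."""
        tr = _single_platform_tracking()
        rng = np.random.default_rng(1)
        pick = rng.random(tr.n_frames) < 0.2
        sp = PosedSpikes("c", tr.t[pick], tr.head_xy[pick, 0],
                         tr.head_xy[pick, 1], tr.head_dir[pick],
                         tr.platform[pick])
        tun = sinks.corrected_tuning(sp, tr, (25.0, -5.0))
        alpha = np.deg2rad(tun.bin_centers[tun.defined])
        w = tun.corrected[tun.defined]
        r_pg = pg.circ_r(alpha, w=w, d=np.deg2rad(15.0))
        # pingouin applies the bin-width correction inside circ_r
        corr = np.deg2rad(15.0) / 2 / np.sin(np.deg2rad(15.0) / 2)
        assert tun.mrl * corr == pytest.approx(float(r_pg), abs=1e-10)
        z_pg, p_pg = pg.circ_rayleigh(alpha, w=w, d=np.deg2rad(15.0))
        assert tun.rayleigh_p == pytest.approx(float(p_pg), rel=1e-6, abs=1e-12)

    def test_sink_at_infinity_approaches_allocentric_tuning(
        self, demo_session, demo_posed
    ):
        cid = demo_session.cells[3].cell_id  # the allocentric HD cell
        sp = demo_posed[cid]
        tr = demo_session.tracking
        far = sinks.corrected_tuning(sp, tr, (1e4, 0.0))
        allo = sinks.allocentric_tuning(sp, tr)
        assert far.mrl == pytest.approx(allo.mrl, abs=0.02)
        assert abs(angular_difference(far.mean_dir, allo.mean_dir)) < 5.0


class TestSinkSearch:
    def test_map_matches_naive_double_loop_oracle(self, demo_session, demo_posed):
        tr = demo_session.tracking
        sp = demo_posed[demo_session.cells[0].cell_id]
        sub = sinks.SinkGrid(
            x=np.linspace(-40, 40, 5), y=np.linspace(-35, 35, 5)
        )
        ctx = sinks.SinkSearchContext(tr, sub)
        mrl_vec, mean_vec = ctx.mrl_of(ctx.spike_hists(sp), ctx.control(sp))
        for ci, (cx, cy) in enumerate(sub.candidates):
            tun = sinks.corrected_tuning(sp, tr, (cx, cy))
            assert mrl_vec[ci] == pytest.approx(tun.mrl, abs=1e-9)
            assert angular_difference(mean_vec[ci], tun.mean_dir) == pytest.approx(
                0.0, abs=1e-9
            )

    def test_recovers_simulated_sink(self, demo_session, demo_posed, demo_grid,
                                     demo_ctx):
        cell = demo_session.cells[0]
        res = sinks.sink_search(
            demo_posed[cell.cell_id], demo_session.tracking, demo_grid, demo_ctx
        )
        err = np.linalg.norm(np.asarray(res.sink_xy) - np.asarray(cell.sink_xy))
        assert err <= 10.0
        assert abs(angular_difference(res.preferred_rd, cell.mu_rd)) <= 15.0
        assert np.all((res.mrl_map >= 0) & (res.mrl_map <= 1))

    def test_translation_invariance(self, demo_session, demo_posed):
        tr = demo_session.tracking
        sp = demo_posed[demo_session.cells[0].cell_id]
        grid = sinks.make_sink_grid(tr, nx=9, ny=7)
        res = sinks.sink_search(sp, tr, grid)
        dx, dy = 1000.0, -500.0
        tr2 = Tracking(tr.t, tr.head_xy + [dx, dy], tr.head_dir,
                       tr.torso_xy + [dx, dy], tr.platform)
        sp2 = PosedSpikes(sp.cell_id, sp.t, sp.x + dx, sp.y + dy, sp.head_dir,
                          sp.platform)
        res2 = sinks.sink_search(sp2, tr2, grid.translate(dx, dy))
        assert np.allclose(res2.mrl_map, res.mrl_map)
        assert res2.sink_xy[0] == pytest.approx(res.sink_xy[0] + dx)

    def test_allocentric_cell_lands_on_grid_boundary(
        self, demo_session, demo_posed, demo_grid, demo_ctx
    ):
        cid = demo_session.cells[3].cell_id
        res = sinks.sink_search(
            demo_posed[cid], demo_session.tracking, demo_grid, demo_ctx
        )
        assert res.boundary


class TestShuffles:
    def test_seeded_null_reproducible_and_bounded(
        self, demo_session, demo_posed, demo_grid, demo_ctx
    ):
        sp = demo_posed[demo_session.cells[0].cell_id]
        tr = demo_session.tracking
        _, _, n1 = sinks.shuffle_test_hd(sp, tr, demo_grid, 25, seed=3,
                                         ctx=demo_ctx, observed_mrl=0.5)
        _, _, n2 = sinks.shuffle_test_hd(sp, tr, demo_grid, 25, seed=3,
                                         ctx=demo_ctx, observed_mrl=0.5)
        assert np.array_equal(n1, n2)
        assert np.all((n1 >= 0) & (n1 <= 1))

    def test_numpy_and_numba_paths_agree(self, demo_session, demo_posed,
                                         demo_grid, demo_ctx):
        sp = demo_posed[demo_session.cells[1].cell_id]
        tr = demo_session.tracking
        _, _, a = sinks.shuffle_test_hd(sp, tr, demo_grid, 20, seed=9,
                                        ctx=demo_ctx, observed_mrl=0.5,
                                        use_numba=True)
        _, _, b = sinks.shuffle_test_hd(sp, tr, demo_grid, 20, seed=9,
                                        ctx=demo_ctx, observed_mrl=0.5,
                                        use_numba=False)
        assert np.allclose(a, b, atol=1e-12)

    def test_perfect_tuning_always_significant(self, demo_session, demo_posed,
                                               demo_grid, demo_ctx):
        sp = demo_posed[demo_session.cells[0].cell_id]
        p, thr, _ = sinks.shuffle_test_hd(
            demo_posed[demo_session.cells[0].cell_id], demo_session.tracking,
            demo_grid, 30, seed=1, ctx=demo_ctx, observed_mrl=1.0,
        )
        assert p == pytest.approx(1 / 31)
        assert thr < 1.0

    def test_too_few_shuffles_rejected(self, demo_session, demo_posed, demo_grid):
        with pytest.raises(ValueError):
            sinks.shuffle_test_hd(
                demo_posed[demo_session.cells[0].cell_id],
                demo_session.tracking, demo_grid, n_shuffles=5,
            )

    def test_timeshift_requires_long_session(self, demo_session, demo_posed):
        tr = demo_session.tracking
        short = Tracking(tr.t[:1000], tr.head_xy[:1000], tr.head_dir[:1000],
                         tr.torso_xy[:1000], tr.platform[:1000])
        with pytest.raises(ValueError):
            sinks.shuffle_test_timeshift(
                demo_posed[demo_session.cells[0].cell_id], short, (0, 0),
                n_shifts=30,
            )

    def test_timeshift_detects_tuned_cell(self, demo_session, demo_posed):
        cell = demo_session.cells[0]
        sp = demo_posed[cell.cell_id]
        tr = demo_session.tracking
        obs = sinks.corrected_tuning(sp, tr, cell.sink_xy).mrl
        p, thr, _ = sinks.shuffle_test_timeshift(
            sp, tr, cell.sink_xy, n_shifts=100, seed=2, observed_mrl=obs
        )
        assert obs > thr and p < 0.05


class TestBurstLevel:
    def test_burst_analysis_sharpens_tuning(self, maze):
        rng = np.random.default_rng(6)
        cell = synth.make_cells(rng, maze, 1, "consink", kappa_rd=(2, 2),
                                base_rate=(3, 3), field_sigma=None)[0]
        ses = synth.generate_session([cell], seed=71, maze=maze, n_trials=10)
        sp = prep.interpolate_pose(ses.spikes[cell.cell_id], ses.tracking,
                                   cell.cell_id, maze)
        grid = sinks.make_sink_grid(ses.tracking, nx=18, ny=15)
        ctx = sinks.SinkSearchContext(ses.tracking, grid)
        spike_res = sinks.sink_search(sp, ses.tracking, grid, ctx)
        burst_res = sinks.burst_sink_search(sp, ses.tracking, grid, maze, ctx)
        assert burst_res is not None
        assert burst_res.mrl > spike_res.mrl
        sep = np.linalg.norm(
            np.asarray(burst_res.sink_xy) - np.asarray(spike_res.sink_xy)
        )
        assert sep <= 15.0

    def test_no_bursts_returns_none(self, maze, demo_session):
        tr = demo_session.tracking
        sparse = PosedSpikes("s", tr.t[::300], tr.head_xy[::300, 0],
                             tr.head_xy[::300, 1], tr.head_dir[::300],
                             tr.platform[::300])
        grid = sinks.make_sink_grid(tr, nx=9, ny=7)
        assert sinks.burst_sink_search(sparse, tr, grid, maze) is None


class TestDownsampling:
    def test_agrees_with_correction_method(self, maze):
        rng = np.random.default_rng(12)
        cell = synth.make_cells(rng, maze, 1, "consink", kappa_rd=(2, 2),
                                base_rate=(2, 2), field_sigma=None)[0]
        ses = synth.generate_session([cell], seed=72, maze=maze, n_trials=13)
        sp = prep.interpolate_pose(ses.spikes[cell.cell_id], ses.tracking,
                                   cell.cell_id, maze)
        grid = sinks.make_sink_grid(ses.tracking)
        ctx = sinks.SinkSearchContext(ses.tracking, grid)
        res = sinks.sink_search(sp, ses.tracking, grid, ctx)
        dv = sinks.downsample_validation(sp, ses.tracking, grid, n_repeats=50,
                                         seed=3, ctx=ctx)
        assert np.linalg.norm(
            np.asarray(dv["mean_sink"]) - np.asarray(res.sink_xy)
        ) <= 10.0
        assert abs(
            angular_difference(dv["mean_preferred_rd"], res.preferred_rd)
        ) <= 15.0
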