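import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consink import prep, synth
from consink.synth import Tracking


def _burst_oracle(times, max_isi=0.25, min_spikes=10, merge_gap=0.5):
    """Straight-line reimplementation: split on large ISIs, filter, merge."""
    times = list(times)
    runs, cur = [], [0]
    for i in range(1, len(times)):
        if times[i] - times[i - 1] <= max_isi:
            cur.append(i)
        else:
            runs.append(cur)
            cur = [i]
    if times:
        runs.append(cur)
    bursts = [r for r in runs if len(r) >= min_spikes]
    merged = True
    while merged and len(bursts) > 1:
        merged = False
        out = [bursts[0]]
        for b in bursts[1:]:
            if times[b[0]] - times[out[-1][-1]] < merge_gap:
                out[-1] = out[-1] + b
                merged = True
            else:
                out.append(b)
        bursts = out
    return [tuple(b) for b in bursts]


class TestBursts:
    def test_single_run_of_twelve(self):
        t = np.arange(12) * 0.1
        bursts = prep.detect_bursts(t)
        assert len(bursts) == 1 and bursts[0].n_spikes == 12

    def test_nine_spikes_is_not_a_burst(self):
        assert prep.detect_bursts(np.arange(9) * 0.1) == []

    def test_two_runs_with_small_gap_merge(self):
        a = np.arange(10) * 0.1
        b = a[-1] + 0.4 + np.arange(10) * 0.1
        bursts = prep.detect_bursts(np.concatenate([a, b]))
        assert len(bursts) == 1 and bursts[0].n_spikes == 20

    def test_single_pass_mode_skips_second_merge(self):
        # three bursts chained by small gaps: fixpoint merges all three
        t = []
        t0 = 0.0
        for _ in range(3):
            t.extend(t0 + np.arange(10) * 0.1)
            t0 = t[-1] + 0.4
        full = prep.detect_bursts(np.asarray(t))
        assert len(full) == 1 and full[0].n_spikes == 30

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_oracle_on_random_trains(self, data):
        n = data.draw(st.integers(0, 120))
        isis = data.draw(
            st.lists(st.floats(0.01, 0.8), min_size=n, max_size=n)
        )
        times = np.cumsum(isis)
        got = prep.detect_bursts(times)
        want = _burst_oracle(times)
        assert [tuple(b.spike_indices) for b in got] == want


class TestExclusionWindows:
    def _series(self, flags, dt=0.01):
        """Construct power/rate series whose conjunction equals *flags*."""
        n = len(flags)
        t = np.arange(n) * dt
        rng = np.random.default_rng(0)
        theta = rng.normal(10.0, 0.1, n)
        ripple = rng.normal(1.0, 0.1, n)
        pop = rng.normal(1.0, 0.1, n)
        theta[flags] = 0.0  # below mean
        ripple[flags] = 10.0  # way above mean + 2 sd
        pop[flags] = 10.0
        return t, theta, ripple, pop

    def test_sixty_ms_conjunction_is_excluded(self):
        flags = np.zeros(1000, bool)
        flags[100:106] = True  # 6 samples at 10 ms = 60 ms
        t, th, ri, po = self._series(flags)
        (win,) = prep.detect_exclusion_windows(t, th, ri, po)
        assert win[1] - win[0] == pytest.approx(0.06)

    def test_forty_ms_conjunction_is_kept(self):
        flags = np.zeros(1000, bool)
        flags[100:104] = True  # 40 ms < the 50-ms minimum
        t, th, ri, po = self._series(flags)
        assert prep.detect_exclusion_windows(t, th, ri, po) == []

    def test_matches_run_length_oracle(self):
        rng = np.random.default_rng(3)
        t = np.arange(4000) * 0.01
        theta = rng.normal(0, 1, t.size)
        ripple = rng.normal(0, 1, t.size)
        pop = rng.normal(0, 1, t.size)
        got = prep.detect_exclusion_windows(t, theta, ripple, pop)
        flag = (
            (theta < theta.mean())
            & (pop > pop.mean() + 2 * pop.std())
            & (ripple > ripple.mean() + 2 * ripple.std())
        )
        # independent run-length scan
        want = []
        run = []
        for i, f in enumerate(list(flag) + [False]):
            if f:
                run.append(i)
            elif run:
                if len(run) * 0.01 >= 0.05 - 1e-12:
                    want.append((t[run[0]], t[run[0]] + len(run) * 0.01))
                run = []
        assert len(got) == len(want)
        for a, b in zip(got, want):
            assert a == pytest.approx(b)

    def test_mismatched_time_base_rejected(self):
        with pytest.raises(ValueError):
            prep.detect_exclusion_windows(
                np.arange(10), np.zeros(10), np.zeros(9), np.zeros(10)
            )

    def test_applying_windows_removes_monotonically(self):
        st_ = np.linspace(0, 10, 101)
        w = [(2.0, 3.0), (5.0, 5.5)]
        once = prep.apply_exclusion_windows(st_, w)
        twice = prep.apply_exclusion_windows(once, w)
        assert len(once) < len(st_)
        assert np.array_equal(once, twice)


class TestPoseInterpolation:
    def _tracking(self):
        t = np.arange(0.0, 10.0, 0.04)
        xy = np.stack([np.linspace(0, 50, t.size), np.linspace(0, -20, t.size)], 1)
        hd = (np.linspace(0, 300, t.size)) % 360
        return Tracking(t, xy, hd, xy.copy(), np.zeros(t.size, int))

    def test_spike_at_frame_time_gets_frame_pose(self):
        tr = self._tracking()
        sp = prep.interpolate_pose(tr.t[[10, 20]], tr, "c")
        assert sp.x == pytest.approx(tr.head_xy[[10, 20], 0])
        assert sp.head_dir == pytest.approx(tr.head_dir[[10, 20]])

    def test_circular_midpoint_across_wrap(self):
        t = np.array([0.0, 1.0])
        xy = np.zeros((2, 2))
        tr = Tracking(t, xy, np.array([350.0, 10.0]), xy, np.zeros(2, int))
        sp = prep.interpolate_pose([0.5], tr, "c")
        assert sp.head_dir[0] == pytest.approx(0.0, abs=1e-9)

    def test_out_of_span_spikes_dropped_with_count(self):
        tr = self._tracking()
        with pytest.warns(UserWarning):
            sp = prep.interpolate_pose([-5.0, 1.0, 2.0, 99.0], tr, "c")
        assert sp.n == 2 and sp.n_dropped == 2

    def test_close_to_nearest_frame_oracle(self):
        tr = self._tracking()
        rng = np.random.default_rng(1)
        st_ = np.sort(rng.uniform(0, tr.t[-1], 1000))
        sp = prep.interpolate_pose(st_, tr, "c")
        idx = np.argmin(np.abs(st_[:, None] - tr.t[None, :]), axis=1)
        step = np.max(np.linalg.norm(np.diff(tr.head_xy, axis=0), axis=1))
        assert np.all(np.abs(sp.x - tr.head_xy[idx, 0]) <= step)
        assert np.all(np.abs(sp.y - tr.head_xy[idx, 1]) <= step)


class TestRateMapsAndScreening:
    def test_counts_conserved(self, demo_session, demo_posed):
        cid = demo_session.cells[0].cell_id
        rm = prep.rate_map(demo_posed[cid], demo_session.tracking)
        assert rm.counts.sum() == demo_posed[cid].n

    def test_field_cell_argmax_near_truth(self, demo_session, demo_posed):
        place = [c for c in demo_session.cells if c.cell_class == "place_only"][0]
        rm = prep.rate_map(
            demo_posed[place.cell_id], demo_session.tracking, smoothing_sigma=1.0
        )
        iy, ix = np.unravel_index(np.nanargmax(rm.rate), rm.rate.shape)
        peak = np.array([rm.x_centers[ix], rm.y_centers[iy]])
        assert np.linalg.norm(peak - np.asarray(place.field_center)) <= place.field_sigma

    def test_spatial_information_closed_forms(self):
        occ = np.ones(16)
        uniform = np.full(16, 3.0)
        assert prep.spatial_information(uniform, occ) == pytest.approx(0.0)
        single = np.zeros(16)
        single[5] = 1.0
        assert prep.spatial_information(single, occ) == pytest.approx(np.log2(16))
        # invariant under uniform rate scaling
        rng = np.random.default_rng(2)
        r = rng.uniform(0, 4, 16)
        assert prep.spatial_information(r, occ) == pytest.approx(
            prep.spatial_information(7.0 * r, occ)
        )

    def test_screen_separates_place_from_uniform(self, maze):
        rng = np.random.default_rng(88)
        place = synth.make_cells(rng, maze, 6, "place_only", base_rate=(2.5, 3.0),
                                 field_sigma=25.0)
        flat = synth.make_cells(rng, maze, 6, "uniform", base_rate=(2.5, 3.0),
                                field_sigma=None)
        ses = synth.generate_session(place + flat, seed=808, maze=maze, n_trials=10)
        hits = {"place_only": 0, "uniform": 0}
        for c in place + flat:
            sp = prep.interpolate_pose(ses.spikes[c.cell_id], ses.tracking,
                                       c.cell_id, maze)
            r = prep.screen_place_cell(sp, ses.tracking, n_shifts=100, seed=5)
            hits[c.cell_class] += r["is_place_cell"]
        assert hits["place_only"] >= 4
        assert hits["uniform"] <= 1
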