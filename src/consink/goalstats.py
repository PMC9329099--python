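"""Goal-referenced statistics: fantail profiles, wait-period firing on
correct versus error choices, goal-shift sink distances, remapping between
task and foraging, place-field centres and behavioural scoring.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._circ import wrap_180
from .prep import PosedSpikes, RateMap, rate_map
from .synth import TaskEvents, Tracking

__all__ = [
    "FantailProfile",
    "RemapReport",
    "fantail",
    "goalward_rate",
    "preferred_direction_rate",
    "compare_correct_error",
    "sink_goal_distances",
    "remapping",
    "place_field_center",
    "behavioural_score",
]

FANTAIL_BINS = 12
FANTAIL_WIDTH = 30.0


def _fantail_bin(angle_deg):
    """12 bins of 30 degrees centred at 0, +-30, ..., 180 (so the central
    bin straddles the goal direction)."""
    return (np.round(np.asarray(angle_deg, float) / FANTAIL_WIDTH).astype(int)) % FANTAIL_BINS


def fantail_bin_centers() -> np.ndarray:
    return wrap_180(FANTAIL_WIDTH * np.arange(FANTAIL_BINS))


@dataclass
class FantailProfile:
    bin_centers: np.ndarray  # degrees relative to goal
    rate: np.ndarray  # per-cell Hz per bin (NaN where never sampled)
    z: np.ndarray  # z-scored across defined bins
    n_cells: int


def _mask_windows(t, windows):
    if windows is None:
        return np.ones(len(t), dtype=bool)
    m = np.zeros(len(t), dtype=bool)
    for t0, t1 in windows:
        m |= (t >= t0) & (t < t1)
    return m


def _rd_to_point(hd_deg, x, y, point):
    brg = np.rad2deg(np.arctan2(point[1] - y, point[0] - x))
    return wrap_180(hd_deg - brg)


def fantail(
    cell_spikes: list,
    tracking: Tracking,
    goal_xy,
    windows=None,
    min_occupancy: float = 1.0,
) -> FantailProfile:
    """Population firing-rate profile over head direction relative to goal.

    Spikes are pooled across ConSink cells; per platform, spikes are binned
    by relative direction to goal and divided by the time spent in that
    (platform, bin); rates are averaged across platforms with equal weight
    and divided by the number of cells; finally z-scored.  (platform, bin)
    cells sampled for less than *min_occupancy* seconds are excluded from
    that platform's average — rate estimates from sub-second occupancy are
    dominated by noise.
    """
    if len(cell_spikes) == 0:
        raise ValueError("need at least one ConSink cell")
    goal_xy = np.asarray(goal_xy, float)
    sx = np.concatenate([s.x for s in cell_spikes])
    sy = np.concatenate([s.y for s in cell_spikes])
    shd = np.concatenate([s.head_dir for s in cell_spikes])
    st = np.concatenate([s.t for s in cell_spikes])
    splat = np.concatenate([s.platform for s in cell_spikes])
    sm = (splat >= 0) & _mask_windows(st, windows)

    fm = (tracking.platform >= 0) & _mask_windows(tracking.t, windows)
    f_rd = _rd_to_point(
        tracking.head_dir[fm], tracking.head_xy[fm, 0], tracking.head_xy[fm, 1], goal_xy
    )
    f_bin = _fantail_bin(f_rd)
    f_plat = tracking.platform[fm]
    n_plat = int(tracking.platform.max()) + 1
    occ = np.zeros((n_plat, FANTAIL_BINS))
    np.add.at(occ, (f_plat, f_bin), tracking.dt)

    s_rd = _rd_to_point(shd[sm], sx[sm], sy[sm], goal_xy)
    s_bin = _fantail_bin(s_rd)
    cnt = np.zeros((n_plat, FANTAIL_BINS))
    np.add.at(cnt, (splat[sm], s_bin), 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        rate_pb = np.where(
            occ >= max(min_occupancy, 1e-12), cnt / np.maximum(occ, 1e-300), np.nan
        )
    visited = occ.sum(axis=1) > 0
    with np.errstate(invalid="ignore"):
        rate = np.nanmean(rate_pb[visited], axis=0) / len(cell_spikes)
    defined = np.isfinite(rate)
    mu = rate[defined].mean()
    sd = rate[defined].std()
    z = np.where(defined, (rate - mu) / max(sd, 1e-300), np.nan)
    order = np.argsort(fantail_bin_centers())
    return FantailProfile(
        bin_centers=fantail_bin_centers()[order],
        rate=rate[order],
        z=z[order],
        n_cells=len(cell_spikes),
    )


# ---------------------------------------------------------------------------
# wait-period firing
# ---------------------------------------------------------------------------
def _cone_rate(spikes, tracking, windows, point, center_deg, tol):
    """Pooled rate over frames within *windows* whose relative direction to
    *point* lies within +-tol of *center_deg*; NaN if no occupancy."""
    fm = _mask_windows(tracking.t, windows)
    f_rd = _rd_to_point(
        tracking.head_dir[fm], tracking.head_xy[fm, 0], tracking.head_xy[fm, 1], point
    )
    occ = np.sum(np.abs(wrap_180(f_rd - center_deg)) <= tol) * tracking.dt
    if occ <= 0:
        return np.nan
    sm = _mask_windows(spikes.t, windows)
    s_rd = _rd_to_point(spikes.head_dir[sm], spikes.x[sm], spikes.y[sm], point)
    n = np.sum(np.abs(wrap_180(s_rd - center_deg)) <= tol)
    return float(n / occ)


def goalward_rate(spikes: PosedSpikes, tracking: Tracking, window, goal_xy, tol=15.0):
    """Firing rate restricted to frames facing the goal (|RD| <= tol)."""
    windows = [window] if np.ndim(window[0]) == 0 else window
    return _cone_rate(spikes, tracking, windows, goal_xy, 0.0, tol)


def preferred_direction_rate(
    spikes: PosedSpikes, tracking: Tracking, window, sink_xy, preferred_rd, tol=15.0
):
    """Firing rate restricted to frames at the cell's preferred relative
    direction to its own ConSink."""
    windows = [window] if np.ndim(window[0]) == 0 else window
    return _cone_rate(spikes, tracking, windows, sink_xy, preferred_rd, tol)


def compare_correct_error(
    cells: list,
    task: TaskEvents,
    tracking: Tracking,
    goal_xy,
    tol: float = 15.0,
    min_trials: int = 5,
) -> dict:
    """Goalward and preferred-direction firing on correct vs error waits.

    *cells* is a list of dicts with keys ``spikes`` (PosedSpikes), ``sink``
    and ``preferred_rd``.  For each wait period (1 and 2), per-cell mean
    rates over correct and error windows are compared across the population
    with Wilcoxon signed-rank tests (two-sided for goalward firing,
    one-sided correct > error for preferred-direction tuning).
    """
    out = {}
    for which in (1, 2):
        cw = task.wait_windows(which, correct=True)
        ew = task.wait_windows(which, correct=False)
        if len(cw) < min_trials or len(ew) < min_trials:
            out[f"wait{which}"] = {"computable": False, "n_correct": len(cw), "n_error": len(ew)}
            continue
        gw_c, gw_e, pd_c, pd_e = [], [], [], []
        for cell in cells:
            sp = cell["spikes"]
            gw_c.append(_cone_rate(sp, tracking, cw, goal_xy, 0.0, tol))
            gw_e.append(_cone_rate(sp, tracking, ew, goal_xy, 0.0, tol))
            pd_c.append(_cone_rate(sp, tracking, cw, cell["sink"], cell["preferred_rd"], tol))
            pd_e.append(_cone_rate(sp, tracking, ew, cell["sink"], cell["preferred_rd"], tol))
        gw_c, gw_e = np.asarray(gw_c), np.asarray(gw_e)
        pd_c, pd_e = np.asarray(pd_c), np.asarray(pd_e)
        ok_g = np.isfinite(gw_c) & np.isfinite(gw_e)
        ok_p = np.isfinite(pd_c) & np.isfinite(pd_e)
        res = {
            "computable": True,
            "n_correct": len(cw),
            "n_error": len(ew),
            "goalward_correct": gw_c,
            "goalward_error": gw_e,
            "median_goalward_diff": float(np.median(gw_c[ok_g] - gw_e[ok_g])),
            "preferred_correct": pd_c,
            "preferred_error": pd_e,
        }
        d = gw_c[ok_g] - gw_e[ok_g]
        res["p_goalward"] = (
            float(stats.wilcoxon(d).pvalue) if np.any(d != 0) else 1.0
        )
        dp = pd_c[ok_p] - pd_e[ok_p]
        res["p_preferred"] = (
            float(stats.wilcoxon(dp, alternative="greater").pvalue)
            if np.any(dp != 0)
            else 1.0
        )
        out[f"wait{which}"] = res
    return out


# ---------------------------------------------------------------------------
# goal-shift distances
# ---------------------------------------------------------------------------
def sink_goal_distances(
    sinks_epoch1: np.ndarray,
    sinks_epoch2: np.ndarray,
    goal1_xy,
    goal2_xy,
    paired: tuple | None = None,
) -> dict:
    """Distances of detected sinks to both goals, with rank tests.

    Per epoch, a one-sided rank-sum test asks whether sinks are closer to
    the epoch's own goal than to the other goal.  If *paired* supplies
    ``(sinks_g1, sinks_g2)`` for the cells with sinks in both epochs, a
    two-sided signed-rank test scores their movement toward the new goal.
    """
    if len(sinks_epoch1) == 0 or len(sinks_epoch2) == 0:
        raise ValueError("empty sink sets")
    g1 = np.asarray(goal1_xy, float)
    g2 = np.asarray(goal2_xy, float)
    s1 = np.asarray(sinks_epoch1, float)
    s2 = np.asarray(sinks_epoch2, float)

    def d(a, g):
        return np.linalg.norm(a - g, axis=1)

    out = {
        "epoch1_dist_goal1": d(s1, g1),
        "epoch1_dist_goal2": d(s1, g2),
        "epoch2_dist_goal1": d(s2, g1),
        "epoch2_dist_goal2": d(s2, g2),
    }
    out["p_epoch1"] = float(
        stats.ranksums(out["epoch1_dist_goal1"], out["epoch1_dist_goal2"], alternative="less").pvalue
    )
    out["p_epoch2"] = float(
        stats.ranksums(out["epoch2_dist_goal2"], out["epoch2_dist_goal1"], alternative="less").pvalue
    )
    if paired is not None:
        p1, p2 = (np.asarray(p, float) for p in paired)
        movement = d(p1, g2) - d(p2, g2)  # positive = moved toward the new goal
        out["paired_movement"] = movement
        out["fraction_moved_toward_goal2"] = float(np.mean(movement > 0))
        out["p_paired"] = (
            float(stats.wilcoxon(movement).pvalue) if np.any(movement != 0) else 1.0
        )
    return out


# ---------------------------------------------------------------------------
# remapping
# ---------------------------------------------------------------------------
@dataclass
class RemapReport:
    pv_corr: np.ndarray  # cross-condition population-vector r per bin
    cell_corr: np.ndarray  # per-cell map correlation across conditions
    baseline_pv_task: np.ndarray
    baseline_pv_forage: np.ndarray
    baseline_cell_task: np.ndarray
    baseline_cell_forage: np.ndarray


def _stack_maps(cell_spikes, tracking, nx, ny, extent):
    maps = [
        rate_map(sp, tracking, nx, ny, extent=extent).rate for sp in cell_spikes
    ]
    return np.stack(maps)  # (cells, ny, nx)


def _pv_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Across-cell Pearson r per spatial bin; NaN where either map stack is
    undefined or degenerate."""
    nc, ny, nx = a.shape
    out = np.full(ny * nx, np.nan)
    af = a.reshape(nc, -1)
    bf = b.reshape(nc, -1)
    for k in range(ny * nx):
        x, y = af[:, k], bf[:, k]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3 and np.std(x[ok]) > 1e-12 and np.std(y[ok]) > 1e-12:
            out[k] = np.corrcoef(x[ok], y[ok])[0, 1]
    return out


def _cell_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    nc = a.shape[0]
    out = np.full(nc, np.nan)
    for k in range(nc):
        x, y = a[k].ravel(), b[k].ravel()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3 and np.std(x[ok]) > 1e-12 and np.std(y[ok]) > 1e-12:
            out[k] = np.corrcoef(x[ok], y[ok])[0, 1]
    return out


def _half_tracking(tracking: Tracking, first: bool) -> Tracking:
    mid = tracking.n_frames // 2
    sl = slice(0, mid) if first else slice(mid, None)
    return Tracking(
        tracking.t[sl],
        tracking.head_xy[sl],
        tracking.head_dir[sl],
        tracking.torso_xy[sl],
        tracking.platform[sl],
    )


def remapping(
    cells_task: list,
    cells_forage: list,
    tracking_task: Tracking,
    tracking_forage: Tracking,
    nx: int = 40,
    ny: int = 32,
) -> RemapReport:
    """Cross-condition remapping against within-condition stability baselines.

    *cells_task* / *cells_forage* hold PosedSpikes for the same cells in
    both conditions.  Rate maps use a common 40 x 32 binning over the union
    field of view; baselines are first-half vs second-half maps within each
    condition.
    """
    allx = np.concatenate([tracking_task.head_xy[:, 0], tracking_forage.head_xy[:, 0]])
    ally = np.concatenate([tracking_task.head_xy[:, 1], tracking_forage.head_xy[:, 1]])
    extent = (allx.min() - 1e-6, allx.max() + 1e-6, ally.min() - 1e-6, ally.max() + 1e-6)

    m_task = _stack_maps(cells_task, tracking_task, nx, ny, extent)
    m_forage = _stack_maps(cells_forage, tracking_forage, nx, ny, extent)

    def _halves(cell_spikes, tracking):
        t_mid = tracking.t[tracking.n_frames // 2]
        h1 = _half_tracking(tracking, True)
        h2 = _half_tracking(tracking, False)
        s1 = [sp.subset(sp.t < t_mid) for sp in cell_spikes]
        s2 = [sp.subset(sp.t >= t_mid) for sp in cell_spikes]
        return (
            _stack_maps(s1, h1, nx, ny, extent),
            _stack_maps(s2, h2, nx, ny, extent),
        )

    t1, t2 = _halves(cells_task, tracking_task)
    f1, f2 = _halves(cells_forage, tracking_forage)
    return RemapReport(
        pv_corr=_pv_corr(m_task, m_forage),
        cell_corr=_cell_corr(m_task, m_forage),
        baseline_pv_task=_pv_corr(t1, t2),
        baseline_pv_forage=_pv_corr(f1, f2),
        baseline_cell_task=_cell_corr(t1, t2),
        baseline_cell_forage=_cell_corr(f1, f2),
    )


# ---------------------------------------------------------------------------
# place-field centres and behaviour
# ---------------------------------------------------------------------------
def place_field_center(rm: RateMap) -> tuple:
    """Rate-weighted centre of mass of a rate map over defined bins."""
    xx, yy = np.meshgrid(rm.x_centers, rm.y_centers)
    ok = np.isfinite(rm.rate)
    w = np.where(ok, rm.rate, 0.0)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("rate map is all zero / undefined")
    return (float((w * xx).sum() / tot), float((w * yy).sum() / tot))


def behavioural_score(task: TaskEvents) -> dict:
    """One-sided binomial test of above-chance choice accuracy (p0 = 0.5);
    equidistant (unscored) choices are excluded."""
    scored = [s for s in task.subtrials if s.correct is not None]
    if not scored:
        raise ValueError("no scored choices")
    n_correct = sum(1 for s in scored if s.correct)
    res = stats.binomtest(n_correct, len(scored), 0.5, alternative="greater")
    return {
        "n_correct": n_correct,
        "n_scored": len(scored),
        "binomial_p": float(res.pvalue),
    }
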