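"""ConSink detection: occupancy-corrected relative-direction tuning over a
grid of candidate sinks, with permutation and time-shift significance tests,
burst-level reanalysis and a downsampling cross-validation of the
occupancy-correction method.

The tuning of a cell to a candidate sink is the binned distribution of
per-spike relative directions (24 x 15 degree bins), divided by a control
distribution built from every video frame: for each platform, the frame
relative-direction histogram is scaled to sum to the cell's spike count on
that platform, and these are summed across platforms.  The corrected
distribution is treated as weights at the bin centres for the mean
resultant length (MRL), circular mean and Rayleigh test; the candidate with
the highest MRL is the cell's ConSink.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._circ import rayleigh_test, resultant, wrap_180
from .geometry import MazeGeometry
from .prep import PosedSpikes, detect_bursts
from .synth import Tracking

try:
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "SinkGrid",
    "CorrectedTuning",
    "ConSinkResult",
    "make_sink_grid",
    "corrected_tuning",
    "allocentric_tuning",
    "uncorrected_mrl",
    "SinkSearchContext",
    "sink_search",
    "shuffle_test_hd",
    "shuffle_test_timeshift",
    "burst_sink_search",
    "detect_consink",
    "downsample_validation",
]

RD_BINS = 24
RD_WIDTH = 360.0 / RD_BINS


def _bin_of(angle_deg, n_bins=RD_BINS):
    """Bin index for angles on the (-180, 180] circle.

    Bin ``b`` covers ``[-180 + b*w, -180 + (b+1)*w)`` with 180 wrapping to
    -180; the same integer formula is used by every code path (scalar
    reference, vectorised search, shuffles) so oracle comparisons are exact.
    """
    w = 360.0 / n_bins
    return (((np.asarray(angle_deg, float) + 180.0) % 360.0) // w).astype(np.int64) % n_bins


def bin_centers(n_bins=RD_BINS):
    w = 360.0 / n_bins
    return -180.0 + w * (np.arange(n_bins) + 0.5)


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------
@dataclass
class SinkGrid:
    """Candidate-sink grid covering the field of view (34 x 29 positions at
    7-cm spacing by default).  Flattened candidate order is row-major in
    (y, x), which fixes argmax tie-breaking to lowest y, then lowest x."""

    x: np.ndarray  # (nx,)
    y: np.ndarray  # (ny,)

    @property
    def nx(self):
        return len(self.x)

    @property
    def ny(self):
        return len(self.y)

    @property
    def n_candidates(self):
        return self.nx * self.ny

    @property
    def candidates(self) -> np.ndarray:
        """(C, 2) candidate coordinates, C = iy * nx + ix."""
        xx, yy = np.meshgrid(self.x, self.y)
        return np.stack([xx.ravel(), yy.ravel()], axis=1)

    def translate(self, dx, dy) -> "SinkGrid":
        return SinkGrid(self.x + dx, self.y + dy)


def make_sink_grid(
    tracking: Tracking | None = None,
    center=None,
    nx: int = 34,
    ny: int = 29,
    spacing: float = 7.0,
) -> SinkGrid:
    """Build the candidate grid, centred on the tracked field of view."""
    if center is None:
        if tracking is None:
            raise ValueError("need tracking or an explicit center")
        lo = tracking.head_xy.min(axis=0)
        hi = tracking.head_xy.max(axis=0)
        center = 0.5 * (lo + hi)
    cx, cy = center
    x = cx + (np.arange(nx) - (nx - 1) / 2.0) * spacing
    y = cy + (np.arange(ny) - (ny - 1) / 2.0) * spacing
    return SinkGrid(x, y)


# ---------------------------------------------------------------------------
# scalar reference tuning
# ---------------------------------------------------------------------------
@dataclass
class CorrectedTuning:
    bin_centers: np.ndarray
    spike_hist: np.ndarray
    control: np.ndarray
    corrected: np.ndarray  # 0 in undefined bins; see `defined`
    defined: np.ndarray
    mrl: float
    mean_dir: float  # degrees in (-180, 180]
    rayleigh_p: float
    n_spikes: int


def _bearing_deg(px, py, sink):
    return np.rad2deg(np.arctan2(sink[1] - py, sink[0] - px))


def _weighted_stats(spike_hist, control, n_bins):
    defined = control > 0
    corrected = np.where(defined, spike_hist / np.maximum(control, 1e-300), 0.0)
    mrl, mean = resultant(bin_centers(n_bins), corrected)
    _, p = rayleigh_test(bin_centers(n_bins), corrected, bin_width_deg=360.0 / n_bins)
    return corrected, defined, float(mrl), float(mean), float(p)


def corrected_tuning(
    spikes: PosedSpikes,
    tracking: Tracking,
    sink,
    n_bins: int = RD_BINS,
) -> CorrectedTuning:
    """Occupancy-corrected relative-direction tuning at one candidate sink
    (readable reference implementation; the grid search uses the vectorised
    :class:`SinkSearchContext`, which must agree with this exactly)."""
    sink = np.asarray(sink, float)
    on = spikes.platform >= 0
    s_rd = spikes.head_dir[on] - _bearing_deg(spikes.x[on], spikes.y[on], sink)
    spike_hist = np.bincount(_bin_of(s_rd, n_bins), minlength=n_bins).astype(float)

    fr_on = tracking.platform >= 0
    f_rd = tracking.head_dir[fr_on] - _bearing_deg(
        tracking.head_xy[fr_on, 0], tracking.head_xy[fr_on, 1], sink
    )
    f_bin = _bin_of(f_rd, n_bins)
    f_plat = tracking.platform[fr_on]
    n_plat = int(tracking.platform.max()) + 1
    frame_hist = np.zeros((n_plat, n_bins))
    np.add.at(frame_hist, (f_plat, f_bin), 1.0)

    spikes_per_platform = np.bincount(spikes.platform[on], minlength=n_plat).astype(float)
    frames_per_platform = frame_hist.sum(axis=1)
    scale = np.where(
        frames_per_platform > 0, spikes_per_platform / np.maximum(frames_per_platform, 1), 0.0
    )
    control = (frame_hist * scale[:, None]).sum(axis=0)
    if not np.any(control > 0):
        raise ValueError("all control bins are zero (cell fired no usable spikes)")
    corrected, defined, mrl, mean, p = _weighted_stats(spike_hist, control, n_bins)
    return CorrectedTuning(
        bin_centers(n_bins), spike_hist, control, corrected, defined, mrl, mean, p,
        int(spike_hist.sum()),
    )


def allocentric_tuning(
    spikes: PosedSpikes, tracking: Tracking, n_bins: int = RD_BINS
) -> CorrectedTuning:
    """Occupancy-corrected allocentric head-direction tuning (same
    correction as for relative direction, applied to head direction)."""
    on = spikes.platform >= 0
    spike_hist = np.bincount(
        _bin_of(wrap_180(spikes.head_dir[on]), n_bins), minlength=n_bins
    ).astype(float)
    fr_on = tracking.platform >= 0
    f_bin = _bin_of(wrap_180(tracking.head_dir[fr_on]), n_bins)
    f_plat = tracking.platform[fr_on]
    n_plat = int(tracking.platform.max()) + 1
    frame_hist = np.zeros((n_plat, n_bins))
    np.add.at(frame_hist, (f_plat, f_bin), 1.0)
    spikes_per_platform = np.bincount(spikes.platform[on], minlength=n_plat).astype(float)
    frames_per_platform = frame_hist.sum(axis=1)
    scale = np.where(
        frames_per_platform > 0, spikes_per_platform / np.maximum(frames_per_platform, 1), 0.0
    )
    control = (frame_hist * scale[:, None]).sum(axis=0)
    corrected, defined, mrl, mean, p = _weighted_stats(spike_hist, control, n_bins)
    return CorrectedTuning(
        bin_centers(n_bins), spike_hist, control, corrected, defined, mrl, mean, p,
        int(spike_hist.sum()),
    )


def uncorrected_mrl(spikes: PosedSpikes, sink) -> float:
    """MRL of the raw per-spike relative-direction distribution (no
    occupancy correction)."""
    sink = np.asarray(sink, float)
    rd = spikes.head_dir - _bearing_deg(spikes.x, spikes.y, sink)
    mrl, _ = resultant(wrap_180(rd))
    return float(mrl)


# ---------------------------------------------------------------------------
# vectorised grid search
# ---------------------------------------------------------------------------
class SinkSearchContext:
    """Per-session precomputation shared by all cells and shuffles.

    Stores, for every candidate sink, the frame relative-direction histogram
    per platform (tensor ``F[c, p, b]``); the control distribution of any
    cell is then a platform-weighted contraction of ``F``.
    """

    def __init__(self, tracking: Tracking, grid: SinkGrid, n_bins: int = RD_BINS,
                 chunk: int = 64):
        self.tracking = tracking
        self.grid = grid
        self.n_bins = n_bins
        self.n_platforms = int(tracking.platform.max()) + 1
        on = tracking.platform >= 0
        self._fx = tracking.head_xy[on, 0]
        self._fy = tracking.head_xy[on, 1]
        self._fhd = tracking.head_dir[on]
        self._fplat = tracking.platform[on]
        self.frames_per_platform = np.bincount(
            self._fplat, minlength=self.n_platforms
        ).astype(float)
        cand = grid.candidates
        C, P, B = grid.n_candidates, self.n_platforms, n_bins
        F = np.zeros((C, P, B), dtype=np.float32)
        pb = (self._fplat * B).astype(np.int64)
        for c0 in range(0, C, chunk):
            cc = cand[c0 : c0 + chunk]
            brg = np.rad2deg(
                np.arctan2(cc[:, 1, None] - self._fy, cc[:, 0, None] - self._fx)
            )
            idx = _bin_of(self._fhd - brg, B) + pb
            flat = (idx + (np.arange(len(cc))[:, None] * (P * B))).ravel()
            F[c0 : c0 + chunk] += np.bincount(
                flat, minlength=len(cc) * P * B
            ).reshape(len(cc), P, B)
        self.F = F
        w = 360.0 / B
        theta = np.deg2rad(bin_centers(B))
        self._e = np.exp(1j * theta)

    # -- per-cell pieces ----------------------------------------------
    def control(self, spikes: PosedSpikes) -> np.ndarray:
        """(C, B) summed control distributions for one cell."""
        on = spikes.platform >= 0
        nsp = np.bincount(spikes.platform[on], minlength=self.n_platforms).astype(float)
        w = np.where(
            self.frames_per_platform > 0,
            nsp / np.maximum(self.frames_per_platform, 1),
            0.0,
        )
        return np.tensordot(self.F, w, axes=([1], [0]))

    def control_from_platform_counts(self, counts: np.ndarray) -> np.ndarray:
        w = np.where(
            self.frames_per_platform > 0,
            counts / np.maximum(self.frames_per_platform, 1),
            0.0,
        )
        return np.tensordot(self.F, w, axes=([1], [0]))

    def spike_bin_base(self, spikes: PosedSpikes) -> np.ndarray:
        """(C, S) float32 base values ``(540 - bearing) / width`` in [24, 48)
        such that the RD bin of spike s at candidate c for head direction hd
        is ``int(base + hd / width) % n_bins``; pre-modulo values lie in
        [24, 72), see :func:`_fold_hist`.  Used by the permutation test and
        the downsampling validation to avoid recomputing bearings."""
        on = spikes.platform >= 0
        sx, sy = spikes.x[on], spikes.y[on]
        cand = self.grid.candidates
        brg = np.rad2deg(
            np.arctan2(cand[:, 1, None] - sy, cand[:, 0, None] - sx)
        )
        w = 360.0 / self.n_bins
        return ((540.0 - brg) / w).astype(np.float32)

    def spike_hists(self, spikes: PosedSpikes) -> np.ndarray:
        """(C, B) spike relative-direction histograms."""
        on = spikes.platform >= 0
        sx, sy, shd = spikes.x[on], spikes.y[on], spikes.head_dir[on]
        cand = self.grid.candidates
        C, B = self.grid.n_candidates, self.n_bins
        out = np.zeros((C, B))
        chunk = 128
        for c0 in range(0, C, chunk):
            cc = cand[c0 : c0 + chunk]
            brg = np.rad2deg(np.arctan2(cc[:, 1, None] - sy, cc[:, 0, None] - sx))
            idx = _bin_of(shd - brg, B)
            flat = (idx + np.arange(len(cc))[:, None] * B).ravel()
            out[c0 : c0 + chunk] = np.bincount(flat, minlength=len(cc) * B).reshape(
                len(cc), B
            )
        return out

    def mrl_of(self, spike_hists: np.ndarray, control: np.ndarray):
        """MRL and circular-mean direction per candidate from histograms."""
        corrected = np.where(control > 0, spike_hists / np.maximum(control, 1e-300), 0.0)
        z = corrected @ self._e
        tot = corrected.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mrl = np.abs(z) / tot
        mean = wrap_180(np.rad2deg(np.angle(z)))
        return mrl, mean


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------
@dataclass
class ConSinkResult:
    cell_id: str
    sink_xy: tuple
    preferred_rd: float
    mrl: float
    mrl_map: np.ndarray  # (ny, nx)
    rayleigh_p: float
    p_hd_shuffle: float | None = None
    hd_threshold: float | None = None
    p_timeshift: float | None = None
    significant: bool | None = None
    used_bursts: bool = False
    boundary: bool = False  # argmax on the grid edge (allocentric suspect)
    tie: bool = False
    n_samples: int = 0

    def to_dict(self) -> dict:
        d = {
            "cell_id": self.cell_id,
            "sink_x": float(self.sink_xy[0]),
            "sink_y": float(self.sink_xy[1]),
            "preferred_rd": float(self.preferred_rd),
            "mrl": float(self.mrl),
            "rayleigh_p": float(self.rayleigh_p),
            "p_hd_shuffle": self.p_hd_shuffle,
            "hd_threshold": self.hd_threshold,
            "p_timeshift": self.p_timeshift,
            "significant": self.significant,
            "used_bursts": self.used_bursts,
            "boundary": self.boundary,
            "tie": self.tie,
            "n_samples": self.n_samples,
        }
        return d


def _argmax_result(cell_id, mrl_c, mean_c, grid, rayleigh_p, n_samples, used_bursts=False):
    mrl_c = np.where(np.isfinite(mrl_c), mrl_c, -1.0)
    best = int(np.argmax(mrl_c))  # first occurrence: lowest y, then x
    tie = int(np.sum(mrl_c == mrl_c[best])) > 1
    iy, ix = divmod(best, grid.nx)
    boundary = ix in (0, grid.nx - 1) or iy in (0, grid.ny - 1)
    return ConSinkResult(
        cell_id=cell_id,
        sink_xy=(float(grid.x[ix]), float(grid.y[iy])),
        preferred_rd=float(mean_c[best]),
        mrl=float(mrl_c[best]),
        mrl_map=mrl_c.reshape(grid.ny, grid.nx),
        rayleigh_p=rayleigh_p,
        used_bursts=used_bursts,
        boundary=boundary,
        tie=tie,
        n_samples=n_samples,
    )


def sink_search(
    spikes: PosedSpikes,
    tracking: Tracking,
    grid: SinkGrid,
    ctx: SinkSearchContext | None = None,
) -> ConSinkResult:
    """Grid search for the candidate sink with maximal corrected MRL."""
    ctx = ctx or SinkSearchContext(tracking, grid)
    hists = ctx.spike_hists(spikes)
    ctrl = ctx.control(spikes)
    mrl_c, mean_c = ctx.mrl_of(hists, ctrl)
    best = int(np.nanargmax(np.where(np.isfinite(mrl_c), mrl_c, -1.0)))
    tun = corrected_tuning(
        spikes, tracking, ctx.grid.candidates[best], n_bins=ctx.n_bins
    )
    n = int(np.sum(spikes.platform >= 0))
    return _argmax_result(spikes.cell_id, mrl_c, mean_c, grid, tun.rayleigh_p, n)


# ---------------------------------------------------------------------------
# significance tests
# ---------------------------------------------------------------------------
if _HAVE_NUMBA:

    @numba.njit(cache=False, fastmath=True)
    def _max_mrl_kernel(base, hdw, perms, ctrl_inv, cos_b, sin_b):  # pragma: no cover
        """Per permutation: rebuild every candidate's corrected tuning from
        the precomputed bin bases and return the maximal MRL over candidates.
        Must agree with the numpy path in `shuffle_test_hd`."""
        K, S = perms.shape
        C, B = ctrl_inv.shape
        out = np.empty(K)
        h = np.zeros(B)
        for k in range(K):
            best = -1.0
            for c in range(C):
                for b in range(B):
                    h[b] = 0.0
                for s in range(S):
                    v = int(base[c, s] + hdw[perms[k, s]]) - B
                    if v >= B:
                        v -= B
                    h[v] += 1.0
                cs = 0.0
                ss = 0.0
                tot = 0.0
                for b in range(B):
                    w = h[b] * ctrl_inv[c, b]
                    cs += w * cos_b[b]
                    ss += w * sin_b[b]
                    tot += w
                if tot > 0.0:
                    r = np.sqrt(cs * cs + ss * ss) / tot
                    if r > best:
                        best = r
            out[k] = best
        return out


def _fold_hist(H):
    """Fold a (C, 3B) histogram of pre-modulo bin values (range B..3B-1, see
    :meth:`SinkSearchContext.spike_bin_base`) onto B relative-direction
    bins."""
    B = H.shape[1] // 3
    return H[:, B : 2 * B] + H[:, 2 * B :]


def shuffle_test_hd(
    spikes: PosedSpikes,
    tracking: Tracking,
    grid: SinkGrid,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed=0,
    ctx: SinkSearchContext | None = None,
    observed_mrl: float | None = None,
    use_numba: bool = True,
):
    """Permutation test: spike head directions are permuted across spikes
    (positions fixed), the full grid search is re-run per shuffle, and the
    maximal MRL over all candidates forms the null distribution.  The cell
    passes if its observed MRL exceeds the null's 100*(1-alpha) percentile.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be at least 20")
    rng = np.random.default_rng(seed)
    ctx = ctx or SinkSearchContext(tracking, grid)
    if observed_mrl is None:
        observed_mrl = sink_search(spikes, tracking, grid, ctx).mrl
    on = spikes.platform >= 0
    hd = spikes.head_dir[on].astype(np.float32)
    base = ctx.spike_bin_base(spikes)  # (C, S)
    ctrl = ctx.control(spikes)
    C, B = grid.n_candidates, ctx.n_bins
    w = np.float32(360.0 / B)
    perms = np.stack([rng.permutation(hd.size) for _ in range(n_shuffles)])
    if _HAVE_NUMBA and use_numba:
        theta = np.deg2rad(bin_centers(B))
        ctrl_inv = np.where(ctrl > 0, 1.0 / np.maximum(ctrl, 1e-300), 0.0)
        null = _max_mrl_kernel(
            base, hd / w, perms, ctrl_inv, np.cos(theta), np.sin(theta)
        )
    else:
        offsets = (np.arange(C, dtype=np.int64) * (3 * B))[:, None]
        e = ctx._e
        null = np.empty(n_shuffles)
        for k in range(n_shuffles):
            v = base + (hd[perms[k]] / w)[None, :]
            idx = v.astype(np.int64) + offsets
            H = np.bincount(idx.ravel(), minlength=C * 3 * B).reshape(C, 3 * B)
            hists = _fold_hist(H)
            corrected = np.where(ctrl > 0, hists / np.maximum(ctrl, 1e-300), 0.0)
            z = corrected @ e
            tot = corrected.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                mrl = np.abs(z) / tot
            null[k] = np.nanmax(mrl)
    threshold = float(np.percentile(null, 100 * (1 - alpha)))
    p = float((1 + np.sum(null >= observed_mrl)) / (1 + n_shuffles))
    return p, threshold, null


def _tuning_mrl_fixed_sink(ctx_small, sx, sy, shd, splat, sink):
    """Corrected MRL at one fixed sink given raw spike pose arrays."""
    frame_hist, frames_per_platform, n_bins = ctx_small
    brg = np.rad2deg(np.arctan2(sink[1] - sy, sink[0] - sx))
    hist = np.bincount(_bin_of(shd - brg, n_bins), minlength=n_bins).astype(float)
    nsp = np.bincount(splat[splat >= 0], minlength=len(frames_per_platform)).astype(float)
    wpl = np.where(frames_per_platform > 0, nsp / np.maximum(frames_per_platform, 1), 0.0)
    control = frame_hist.T @ wpl
    corrected = np.where(control > 0, hist / np.maximum(control, 1e-300), 0.0)
    mrl, _ = resultant(bin_centers(n_bins), corrected)
    return float(mrl)


def shuffle_test_timeshift(
    spikes: PosedSpikes,
    tracking: Tracking,
    sink,
    n_shifts: int = 1000,
    min_shift: float = 60.0,
    alpha: float = 0.05,
    seed=0,
    observed_mrl: float | None = None,
    n_bins: int = RD_BINS,
):
    """Circular time-shift control: the spike train is shifted relative to
    the tracking by a uniform offset in [min_shift, T - min_shift] and the
    tuning to the *fixed* sink recomputed per shift."""
    t0, t1 = tracking.t[0], tracking.t[-1]
    T = t1 - t0
    if T < 2 * min_shift:
        raise ValueError("session shorter than twice the minimum shift")
    rng = np.random.default_rng(seed)
    sink = np.asarray(sink, float)

    fr_on = tracking.platform >= 0
    n_plat = int(tracking.platform.max()) + 1
    brg_f = np.rad2deg(
        np.arctan2(
            sink[1] - tracking.head_xy[fr_on, 1], sink[0] - tracking.head_xy[fr_on, 0]
        )
    )
    f_bin = _bin_of(tracking.head_dir[fr_on] - brg_f, n_bins)
    frame_hist = np.zeros((n_plat, n_bins))
    np.add.at(frame_hist, (tracking.platform[fr_on], f_bin), 1.0)
    frames_per_platform = frame_hist.sum(axis=1)
    small = (frame_hist, frames_per_platform, n_bins)

    if observed_mrl is None:
        observed_mrl = _tuning_mrl_fixed_sink(
            small, spikes.x, spikes.y, spikes.head_dir, spikes.platform, sink
        )
    null = np.empty(n_shifts)
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(tracking.head_dir)))
    for k in range(n_shifts):
        sh = rng.uniform(min_shift, T - min_shift)
        st = t0 + (spikes.t - t0 + sh) % T
        sx = np.interp(st, tracking.t, tracking.head_xy[:, 0])
        sy = np.interp(st, tracking.t, tracking.head_xy[:, 1])
        shd = np.interp(st, tracking.t, unwrapped) % 360.0
        fi = np.clip(
            np.searchsorted(tracking.t, st, side="right") - 1, 0, tracking.n_frames - 1
        )
        splat = tracking.platform[fi]
        null[k] = _tuning_mrl_fixed_sink(small, sx, sy, shd, splat, sink)
    threshold = float(np.percentile(null, 100 * (1 - alpha)))
    p = float((1 + np.sum(null >= observed_mrl)) / (1 + n_shifts))
    return p, threshold, null


# ---------------------------------------------------------------------------
# burst-level analysis
# ---------------------------------------------------------------------------
def _burst_samples(spikes: PosedSpikes, bursts):
    member = np.full(spikes.n, -1, dtype=np.int64)
    for j, b in enumerate(bursts):
        member[b.spike_indices] = j
    sel = member >= 0
    return member[sel], sel


def burst_sink_search(
    spikes: PosedSpikes,
    tracking: Tracking,
    grid: SinkGrid,
    maze: MazeGeometry,
    ctx: SinkSearchContext | None = None,
    bursts=None,
) -> ConSinkResult | None:
    """Re-run the sink search with one sample per burst: the burst's
    relative direction at each candidate is the circular mean of its member
    spikes' relative directions, and its position is the mean spike
    position.  Returns None if the cell has no bursts."""
    ctx = ctx or SinkSearchContext(tracking, grid)
    if bursts is None:
        bursts = detect_bursts(spikes.t)
    if len(bursts) == 0:
        return None
    member, sel = _burst_samples(spikes, bursts)
    n_b = len(bursts)
    bx = np.bincount(member, weights=spikes.x[sel], minlength=n_b) / np.bincount(
        member, minlength=n_b
    )
    by = np.bincount(member, weights=spikes.y[sel], minlength=n_b) / np.bincount(
        member, minlength=n_b
    )
    bplat = maze.platform_of(np.stack([bx, by], axis=1))

    cand = ctx.grid.candidates
    C, B = grid.n_candidates, ctx.n_bins
    sx, sy = spikes.x[sel], spikes.y[sel]
    hd_rad = np.deg2rad(spikes.head_dir[sel])
    hists = np.zeros((C, B))
    chunk = 64
    for c0 in range(0, C, chunk):
        cc = cand[c0 : c0 + chunk]
        brg = np.arctan2(cc[:, 1, None] - sy, cc[:, 0, None] - sx)
        rd = hd_rad[None, :] - brg
        cosr, sinr = np.cos(rd), np.sin(rd)
        flat = (member[None, :] + np.arange(len(cc))[:, None] * n_b).ravel()
        zc = np.bincount(flat, weights=cosr.ravel(), minlength=len(cc) * n_b)
        zs = np.bincount(flat, weights=sinr.ravel(), minlength=len(cc) * n_b)
        ang = np.rad2deg(np.arctan2(zs, zc)).reshape(len(cc), n_b)
        idx = _bin_of(ang, B)
        flat2 = (idx + np.arange(len(cc))[:, None] * B).ravel()
        hists[c0 : c0 + chunk] = np.bincount(
            flat2, minlength=len(cc) * B
        ).reshape(len(cc), B)

    counts = np.bincount(bplat[bplat >= 0], minlength=ctx.n_platforms).astype(float)
    ctrl = ctx.control_from_platform_counts(counts)
    mrl_c, mean_c = ctx.mrl_of(hists, ctrl)
    mrl_safe = np.where(np.isfinite(mrl_c), mrl_c, -1.0)
    best = int(np.argmax(mrl_safe))
    corrected = np.where(ctrl[best] > 0, hists[best] / np.maximum(ctrl[best], 1e-300), 0.0)
    _, p_ray = rayleigh_test(bin_centers(B), corrected, bin_width_deg=360.0 / B)
    res = _argmax_result(
        spikes.cell_id, mrl_c, mean_c, grid, p_ray, n_b, used_bursts=True
    )
    return res


def _burst_mrl_fixed_sink(spikes, member, sel, bplat, small, sink, n_bins, hd=None):
    sx, sy = spikes.x[sel], spikes.y[sel]
    hd_use = spikes.head_dir[sel] if hd is None else hd
    brg = np.rad2deg(np.arctan2(sink[1] - sy, sink[0] - sx))
    rd = np.deg2rad(hd_use - brg)
    n_b = int(member.max()) + 1
    zc = np.bincount(member, weights=np.cos(rd), minlength=n_b)
    zs = np.bincount(member, weights=np.sin(rd), minlength=n_b)
    ang = np.rad2deg(np.arctan2(zs, zc))
    hist = np.bincount(_bin_of(ang, n_bins), minlength=n_bins).astype(float)
    frame_hist, frames_per_platform, _ = small
    counts = np.bincount(bplat[bplat >= 0], minlength=len(frames_per_platform)).astype(float)
    wpl = np.where(frames_per_platform > 0, counts / np.maximum(frames_per_platform, 1), 0.0)
    control = frame_hist.T @ wpl
    corrected = np.where(control > 0, hist / np.maximum(control, 1e-300), 0.0)
    mrl, _ = resultant(bin_centers(n_bins), corrected)
    return float(mrl)


# ---------------------------------------------------------------------------
# full per-cell pipeline
# ---------------------------------------------------------------------------
def detect_consink(
    spikes: PosedSpikes,
    tracking: Tracking,
    grid: SinkGrid,
    maze: MazeGeometry,
    n_shuffles: int = 1000,
    n_shifts: int = 1000,
    min_shift: float = 60.0,
    alpha: float = 0.05,
    seed=0,
    ctx: SinkSearchContext | None = None,
    do_bursts: bool = True,
) -> ConSinkResult:
    """Spike-level sink search with both significance tests, plus the
    burst-level reanalysis; when both analyses are significant, the burst
    result is carried forward."""
    from .synth import as_seed_sequence

    ss = as_seed_sequence(seed)
    s_hd, s_ts, s_hd_b, s_ts_b = [s.generate_state(1)[0] for s in ss.spawn(4)]
    ctx = ctx or SinkSearchContext(tracking, grid)

    res = sink_search(spikes, tracking, grid, ctx)
    p_hd, thr, _ = shuffle_test_hd(
        spikes, tracking, grid, n_shuffles, alpha, s_hd, ctx, res.mrl
    )
    p_ts, _, _ = shuffle_test_timeshift(
        spikes, tracking, res.sink_xy, n_shifts, min_shift, alpha, s_ts, res.mrl
    )
    res.p_hd_shuffle, res.hd_threshold, res.p_timeshift = p_hd, thr, p_ts
    res.significant = bool(
        p_hd < alpha and p_ts < alpha and res.rayleigh_p < alpha
    )

    if not do_bursts:
        return res
    bursts = detect_bursts(spikes.t)
    bres = (
        burst_sink_search(spikes, tracking, grid, maze, ctx, bursts)
        if bursts
        else None
    )
    if bres is None:
        return res
    # significance of the burst-level analysis
    member, sel = _burst_samples(spikes, bursts)
    n_b = len(bursts)
    bx = np.bincount(member, weights=spikes.x[sel], minlength=n_b) / np.bincount(
        member, minlength=n_b
    )
    by = np.bincount(member, weights=spikes.y[sel], minlength=n_b) / np.bincount(
        member, minlength=n_b
    )
    bplat = maze.platform_of(np.stack([bx, by], axis=1))
    sink = np.asarray(bres.sink_xy, float)
    fr_on = tracking.platform >= 0
    n_plat = int(tracking.platform.max()) + 1
    brg_f = np.rad2deg(
        np.arctan2(
            sink[1] - tracking.head_xy[fr_on, 1], sink[0] - tracking.head_xy[fr_on, 0]
        )
    )
    f_bin = _bin_of(tracking.head_dir[fr_on] - brg_f, ctx.n_bins)
    frame_hist = np.zeros((n_plat, ctx.n_bins))
    np.add.at(frame_hist, (tracking.platform[fr_on], f_bin), 1.0)
    small = (frame_hist, frame_hist.sum(axis=1), ctx.n_bins)

    rng = np.random.default_rng(s_hd_b)
    null = np.empty(n_shuffles)
    hd_all = spikes.head_dir[sel]
    for k in range(n_shuffles):
        null[k] = _burst_mrl_fixed_sink(
            spikes, member, sel, bplat, small, sink, ctx.n_bins,
            hd=hd_all[rng.permutation(hd_all.size)],
        )
    p_hd_b = float((1 + np.sum(null >= bres.mrl)) / (1 + n_shuffles))

    rng = np.random.default_rng(s_ts_b)
    t0, t1 = tracking.t[0], tracking.t[-1]
    T = t1 - t0
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(tracking.head_dir)))
    null_ts = np.empty(n_shifts)
    for k in range(n_shifts):
        sh = rng.uniform(min_shift, T - min_shift)
        st = t0 + (spikes.t[sel] - t0 + sh) % T
        sx = np.interp(st, tracking.t, tracking.head_xy[:, 0])
        sy = np.interp(st, tracking.t, tracking.head_xy[:, 1])
        shd = np.interp(st, tracking.t, unwrapped) % 360.0
        fake = PosedSpikes(spikes.cell_id, st, sx, sy, shd, None)
        # burst positions follow the shifted pose
        bx_k = np.bincount(member, weights=sx, minlength=n_b) / np.bincount(
            member, minlength=n_b
        )
        by_k = np.bincount(member, weights=sy, minlength=n_b) / np.bincount(
            member, minlength=n_b
        )
        bplat_k = maze.platform_of(np.stack([bx_k, by_k], axis=1))
        null_ts[k] = _burst_mrl_fixed_sink(
            fake, member, np.ones(st.size, bool), bplat_k, small, sink, ctx.n_bins
        )
    p_ts_b = float((1 + np.sum(null_ts >= bres.mrl)) / (1 + n_shifts))

    bres.p_hd_shuffle = p_hd_b
    bres.p_timeshift = p_ts_b
    bres.significant = bool(
        p_hd_b < alpha and p_ts_b < alpha and bres.rayleigh_p < alpha
    )
    if res.significant and bres.significant:
        return bres  # burst tuning carried forward when both are significant
    return res


# ---------------------------------------------------------------------------
# downsampling validation
# ---------------------------------------------------------------------------
def downsample_validation(
    spikes: PosedSpikes,
    tracking: Tracking,
    grid: SinkGrid,
    n_repeats: int = 1000,
    n_hd_bins: int = 24,
    seed=0,
    ctx: SinkSearchContext | None = None,
):
    """Cross-check of the occupancy-correction method by downsampling.

    Per platform, spikes are binned by allocentric head direction (24 x 15
    degree bins) and kept with probability proportional to the inverse of
    the directional occupancy of their bin, equalising directional sampling;
    the (uncorrected) sink search is re-run on each downsampled train and
    the results averaged over repeats.
    """
    rng = np.random.default_rng(seed)
    ctx = ctx or SinkSearchContext(tracking, grid)
    on = spikes.platform >= 0
    s_hd_bin = _bin_of(wrap_180(spikes.head_dir[on]), n_hd_bins)
    s_plat = spikes.platform[on]
    fr_on = tracking.platform >= 0
    f_hd_bin = _bin_of(wrap_180(tracking.head_dir[fr_on]), n_hd_bins)
    f_plat = tracking.platform[fr_on]
    n_plat = ctx.n_platforms
    occ = np.zeros((n_plat, n_hd_bins))
    np.add.at(occ, (f_plat, f_hd_bin), tracking.dt)
    spk_counts = np.zeros((n_plat, n_hd_bins))
    np.add.at(spk_counts, (s_plat, s_hd_bin), 1.0)

    keep_p = np.zeros((n_plat, n_hd_bins))
    for p in range(n_plat):
        fired = (spk_counts[p] > 0) & (occ[p] > 0)
        if not np.any(fired):
            continue
        keep_p[p, fired] = occ[p, fired].min() / occ[p, fired]
    q = keep_p[s_plat, s_hd_bin]

    base = ctx.spike_bin_base(spikes)  # (C, S) for on-platform spikes
    hd = spikes.head_dir[on]
    C, B = grid.n_candidates, ctx.n_bins
    w = 360.0 / B
    e = ctx._e
    sinks = np.empty((n_repeats, 2))
    dirs = np.empty(n_repeats)
    mrls = np.empty(n_repeats)
    v_all = (base + (hd / w)[None, :]).astype(np.float32)
    for k in range(n_repeats):
        keep = rng.random(q.size) < q
        idx = v_all[:, keep].astype(np.int64)
        H = np.bincount(
            (idx + (np.arange(C, dtype=np.int64) * (3 * B))[:, None]).ravel(),
            minlength=C * 3 * B,
        ).reshape(C, 3 * B)
        hists = _fold_hist(H)
        z = hists @ e
        tot = hists.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mrl = np.abs(z) / tot
        mrl = np.where(np.isfinite(mrl), mrl, -1.0)
        best = int(np.argmax(mrl))
        iy, ix = divmod(best, grid.nx)
        sinks[k] = (grid.x[ix], grid.y[iy])
        dirs[k] = wrap_180(np.rad2deg(np.angle(z[best])))
        mrls[k] = mrl[best]
    _, mean_dir = resultant(dirs)
    return {
        "mean_sink": tuple(sinks.mean(axis=0)),
        "mean_preferred_rd": float(mean_dir),
        "mean_mrl": float(mrls.mean()),
    }
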