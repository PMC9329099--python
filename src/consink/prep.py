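"""Spike-train preprocessing: pose interpolation, sharp-wave-ripple
exclusion windows, burst detection, rate maps and place-cell screening.

Spectral estimation of the theta/ripple band power from raw LFP is out of
scope; :func:`detect_exclusion_windows` consumes precomputed power series.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._circ import circular_interp, circular_mean
from .synth import Tracking
from .geometry import MazeGeometry

__all__ = [
    "PosedSpikes",
    "Burst",
    "RateMap",
    "interpolate_pose",
    "detect_exclusion_windows",
    "apply_exclusion_windows",
    "detect_bursts",
    "rate_map",
    "spatial_information",
    "coherence",
    "screen_place_cell",
    "MIN_SPIKES_PER_CONDITION",
]

MIN_SPIKES_PER_CONDITION = 500


@dataclass
class PosedSpikes:
    """Spike times with interpolated pose at each spike."""

    cell_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    head_dir: np.ndarray  # degrees [0, 360)
    platform: np.ndarray  # platform at spike time (torso-based), -1 off maze
    n_dropped: int = 0  # spikes outside the tracking span

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        return np.stack([self.x, self.y], axis=1)

    def subset(self, mask) -> "PosedSpikes":
        return PosedSpikes(
            self.cell_id,
            self.t[mask],
            self.x[mask],
            self.y[mask],
            self.head_dir[mask],
            self.platform[mask],
            self.n_dropped,
        )


def interpolate_pose(
    spike_times, tracking: Tracking, cell_id: str = "", maze: MazeGeometry | None = None
) -> PosedSpikes:
    """Linear interpolation of head position and shortest-arc interpolation
    of head direction at each spike time; spikes outside the tracking span
    are dropped (counted in ``n_dropped``)."""
    st = np.sort(np.asarray(spike_times, float))
    inside = (st >= tracking.t[0]) & (st <= tracking.t[-1])
    n_dropped = int(np.sum(~inside))
    if n_dropped:
        warnings.warn(f"{n_dropped} spikes outside the tracking span were dropped")
    st = st[inside]
    if st.size == 0 and n_dropped:
        raise ValueError("no overlap between spikes and tracking")
    x = np.interp(st, tracking.t, tracking.head_xy[:, 0])
    y = np.interp(st, tracking.t, tracking.head_xy[:, 1])
    hd = circular_interp(st, tracking.t, tracking.head_dir)
    # platform occupancy is frame-wise (torso-based): take the covering frame
    idx = np.clip(
        np.searchsorted(tracking.t, st, side="right") - 1, 0, tracking.n_frames - 1
    )
    platform = tracking.platform[idx]
    return PosedSpikes(cell_id, st, x, y, hd, platform, n_dropped)


# ---------------------------------------------------------------------------
# exclusion windows
# ---------------------------------------------------------------------------
def detect_exclusion_windows(
    t,
    theta_power,
    ripple_power,
    pop_rate,
    min_duration: float = 0.05,
) -> list:
    """Sharp-wave-ripple exclusion intervals.

    A sample is flagged when simultaneously theta power is below its mean,
    population rate exceeds mean + 2 s.d. and ripple power exceeds
    mean + 2 s.d.; flagged runs lasting at least *min_duration* (50 ms by
    default) become exclusion intervals ``(t_start, t_end)``.
    """
    t = np.asarray(t, float)
    series = [np.asarray(s, float) for s in (theta_power, ripple_power, pop_rate)]
    if any(len(s) != len(t) for s in series):
        raise ValueError("power/rate series must share the time base")
    theta, ripple, pop = series
    flag = (
        (theta < theta.mean())
        & (pop > pop.mean() + 2 * pop.std())
        & (ripple > ripple.mean() + 2 * ripple.std())
    )
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    out = []
    k = 0
    n = len(flag)
    while k < n:
        if flag[k]:
            j = k
            while j + 1 < n and flag[j + 1]:
                j += 1
            duration = (j - k + 1) * dt
            if duration >= min_duration - 1e-12:
                out.append((t[k], t[k] + duration))
            k = j + 1
        else:
            k += 1
    return out


def apply_exclusion_windows(spike_times, windows) -> np.ndarray:
    """Remove spikes inside any exclusion interval (order preserved)."""
    st = np.asarray(spike_times, float)
    keep = np.ones(st.size, dtype=bool)
    for t0, t1 in windows:
        keep &= ~((st >= t0) & (st < t1))
    return st[keep]


# ---------------------------------------------------------------------------
# bursts
# ---------------------------------------------------------------------------
@dataclass
class Burst:
    spike_indices: np.ndarray
    t_start: float
    t_end: float

    @property
    def n_spikes(self) -> int:
        return len(self.spike_indices)


def detect_bursts(
    spike_times,
    max_isi: float = 0.25,
    min_spikes: int = 10,
    merge_gap: float = 0.5,
    single_pass: bool = False,
) -> list:
    """Bursts: maximal runs of >= *min_spikes* spikes with inter-spike
    intervals <= *max_isi*; bursts separated by < *merge_gap* are combined
    (iterated to a fixpoint unless ``single_pass``)."""
    st = np.asarray(spike_times, float)
    if st.size and np.any(np.diff(st) < 0):
        raise ValueError("spike times must be sorted")
    if st.size == 0:
        return []
    isi = np.diff(st)
    breaks = np.flatnonzero(isi > max_isi)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [st.size - 1]])
    runs = [(s, e) for s, e in zip(starts, ends) if e - s + 1 >= min_spikes]
    bursts = [list(range(s, e + 1)) for s, e in runs]

    changed = True
    while changed and len(bursts) > 1:
        changed = False
        merged = [bursts[0]]
        for b in bursts[1:]:
            if st[b[0]] - st[merged[-1][-1]] < merge_gap:
                merged[-1] = merged[-1] + b
                changed = True
            else:
                merged.append(b)
        bursts = merged
        if single_pass:
            break
    return [
        Burst(np.asarray(b, int), float(st[b[0]]), float(st[b[-1]])) for b in bursts
    ]


def burst_summary(bursts, spikes: PosedSpikes):
    """Mean position and circular-mean head direction per burst."""
    out = []
    for b in bursts:
        idx = b.spike_indices
        out.append(
            {
                "t_start": b.t_start,
                "t_end": b.t_end,
                "n": b.n_spikes,
                "mean_x": float(spikes.x[idx].mean()),
                "mean_y": float(spikes.y[idx].mean()),
                "mean_hd": float(circular_mean(spikes.head_dir[idx]) % 360.0),
            }
        )
    return out


# ---------------------------------------------------------------------------
# rate maps and screening
# ---------------------------------------------------------------------------
@dataclass
class RateMap:
    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy: np.ndarray  # seconds, shape (ny, nx)
    counts: np.ndarray
    rate: np.ndarray  # Hz, NaN where occupancy is zero

    @property
    def x_centers(self):
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self):
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


def _extent(tracking: Tracking, extent=None):
    if extent is not None:
        return extent
    x, y = tracking.head_xy[:, 0], tracking.head_xy[:, 1]
    pad = 1e-6
    return (x.min() - pad, x.max() + pad, y.min() - pad, y.max() + pad)


def rate_map(
    spikes: PosedSpikes,
    tracking: Tracking,
    nx: int = 40,
    ny: int = 32,
    smoothing_sigma: float | None = None,
    extent=None,
) -> RateMap:
    """Occupancy-normalised firing-rate map on an ``ny x nx`` grid.

    Smoothing (in bins) is applied to counts and occupancy separately before
    the division, so smoothed rates remain occupancy-weighted.
    """
    x0, x1, y0, y1 = _extent(tracking, extent)
    xe = np.linspace(x0, x1, nx + 1)
    ye = np.linspace(y0, y1, ny + 1)
    dt = tracking.dt
    occ, _, _ = np.histogram2d(
        tracking.head_xy[:, 1], tracking.head_xy[:, 0], bins=[ye, xe]
    )
    occ = occ * dt
    if occ.sum() <= 0:
        raise ValueError("zero total occupancy on the requested extent")
    counts, _, _ = np.histogram2d(spikes.y, spikes.x, bins=[ye, xe])
    if smoothing_sigma:
        counts_s = ndimage.gaussian_filter(counts, smoothing_sigma)
        occ_s = ndimage.gaussian_filter(occ, smoothing_sigma)
    else:
        counts_s, occ_s = counts, occ
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ_s > 1e-12, counts_s / np.maximum(occ_s, 1e-300), np.nan)
    return RateMap(xe, ye, occ, counts, rate)


def spatial_information(rate: np.ndarray, occupancy: np.ndarray) -> float:
    """Skaggs spatial information in bits/spike:
    ``sum_i p_i (r_i / rbar) log2(r_i / rbar)`` over defined bins."""
    occ = np.asarray(occupancy, float).ravel()
    r = np.asarray(rate, float).ravel()
    ok = (occ > 0) & np.isfinite(r)
    p = occ[ok] / occ[ok].sum()
    r = r[ok]
    rbar = float(np.sum(p * r))
    if rbar <= 0:
        return 0.0
    ratio = r / rbar
    terms = np.where(ratio > 0, p * ratio * np.log2(np.maximum(ratio, 1e-300)), 0.0)
    return float(terms.sum())


def coherence(rate: np.ndarray) -> float:
    """Spatial coherence: Pearson correlation between each defined bin's
    rate and the mean rate of its (up to 8) defined neighbours, computed on
    the unsmoothed map."""
    r = np.asarray(rate, float)
    defined = np.isfinite(r)
    filled = np.where(defined, r, 0.0)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nbr_sum = ndimage.convolve(filled, kernel, mode="constant")
    nbr_cnt = ndimage.convolve(defined.astype(float), kernel, mode="constant")
    ok = defined & (nbr_cnt > 0)
    if ok.sum() < 3:
        return np.nan
    nbr_mean = nbr_sum[ok] / nbr_cnt[ok]
    a, b = r[ok], nbr_mean
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _time_shifted(spike_times, t0, t1, shift):
    return t0 + (np.asarray(spike_times) - t0 + shift) % (t1 - t0)


def screen_place_cell(
    spikes: PosedSpikes,
    tracking: Tracking,
    n_shifts: int = 200,
    min_shift: float = 60.0,
    nx: int = 40,
    ny: int = 32,
    alpha: float = 0.05,
    seed=0,
) -> dict:
    """Place-cell screen: spatial information and coherence must both exceed
    the 95th percentile of a circular time-shift null (minimum shift 60 s)."""
    rng = np.random.default_rng(seed)
    extent = _extent(tracking)
    rm = rate_map(spikes, tracking, nx, ny, extent=extent)
    si_obs = spatial_information(rm.rate, rm.occupancy)
    coh_obs = coherence(rm.rate)
    t0, t1 = tracking.t[0], tracking.t[-1]
    T = t1 - t0
    if T < 2 * min_shift:
        raise ValueError("session too short for the time-shift null")
    si_null = np.empty(n_shifts)
    coh_null = np.empty(n_shifts)
    for k in range(n_shifts):
        sh = rng.uniform(min_shift, T - min_shift)
        st = _time_shifted(spikes.t, t0, t1, sh)
        x = np.interp(st, tracking.t, tracking.head_xy[:, 0])
        y = np.interp(st, tracking.t, tracking.head_xy[:, 1])
        fake = PosedSpikes(spikes.cell_id, st, x, y, np.zeros_like(st), None)
        rm_k = rate_map(fake, tracking, nx, ny, extent=extent)
        si_null[k] = spatial_information(rm_k.rate, rm_k.occupancy)
        coh_null[k] = coherence(rm_k.rate)
    q = 100 * (1 - alpha)
    si_thr = float(np.percentile(si_null, q))
    coh_thr = float(np.nanpercentile(coh_null, q))
    is_pc = bool(
        np.isfinite(coh_obs) and si_obs > si_thr and coh_obs > coh_thr
    )
    return {
        "spatial_info": si_obs,
        "coherence": coh_obs,
        "si_threshold": si_thr,
        "coherence_threshold": coh_thr,
        "is_place_cell": is_pc,
    }
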