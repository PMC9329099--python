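"""Vector fields: per-cell spatial binning of spike head directions,
platform-level population vector fields, and population-sink localization.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._circ import resultant, wrap_180
from .geometry import MazeGeometry
from .prep import PosedSpikes
from .sinks import SinkGrid, _bin_of, bin_centers
from .synth import Tracking

__all__ = [
    "VectorField",
    "PopulationSink",
    "cell_vector_field",
    "population_vector_field",
    "population_sink",
]

MIN_SPIKES_PER_BIN = 20  # cell-field bins need more than this many spikes


@dataclass
class VectorField:
    """Per-bin circular-mean allocentric firing direction.

    For cell fields, bins are a regular spatial grid (20 x 16 by default) and
    ``positions`` holds bin centres; for population fields, bins are maze
    platforms and ``positions`` holds platform centres.  ``direction`` is in
    degrees [0, 360), NaN where undefined; ``length`` is the resultant vector
    length (for population fields, the summed-vector magnitude)."""

    positions: np.ndarray  # (n, 2)
    direction: np.ndarray  # (n,)
    length: np.ndarray  # (n,)
    n_spikes: np.ndarray  # (n,)


@dataclass
class PopulationSink:
    sink_xy: tuple
    mrl: float
    mrl_map: np.ndarray  # (ny, nx)
    preferred_rd: float


def cell_vector_field(
    spikes: PosedSpikes,
    tracking: Tracking,
    nx: int = 20,
    ny: int = 16,
    min_spikes: int = MIN_SPIKES_PER_BIN,
    extent=None,
) -> VectorField:
    """Circular-mean spike head direction on an ``ny x nx`` spatial grid;
    bins with ``<= min_spikes`` spikes are undefined."""
    if extent is None:
        x0, x1 = tracking.head_xy[:, 0].min(), tracking.head_xy[:, 0].max()
        y0, y1 = tracking.head_xy[:, 1].min(), tracking.head_xy[:, 1].max()
    else:
        x0, x1, y0, y1 = extent
    xe = np.linspace(x0, x1 + 1e-9, nx + 1)
    ye = np.linspace(y0, y1 + 1e-9, ny + 1)
    ix = np.clip(np.searchsorted(xe, spikes.x, side="right") - 1, 0, nx - 1)
    iy = np.clip(np.searchsorted(ye, spikes.y, side="right") - 1, 0, ny - 1)
    flat = iy * nx + ix
    n = nx * ny
    counts = np.bincount(flat, minlength=n).astype(float)
    ang = np.deg2rad(spikes.head_dir)
    zc = np.bincount(flat, weights=np.cos(ang), minlength=n)
    zs = np.bincount(flat, weights=np.sin(ang), minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        length = np.hypot(zc, zs) / counts
    direction = np.rad2deg(np.arctan2(zs, zc)) % 360.0
    undef = counts <= min_spikes
    direction[undef] = np.nan
    length[undef] = np.nan
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    xx, yy = np.meshgrid(xc, yc)
    return VectorField(
        positions=np.stack([xx.ravel(), yy.ravel()], axis=1),
        direction=direction,
        length=length,
        n_spikes=counts,
    )


def population_vector_field(
    cells: list,
    tracking: Tracking,
    maze: MazeGeometry,
) -> VectorField:
    """Platform-level population vector field.

    *cells* is a list of ``(spikes, mrl)`` pairs for the significant ConSink
    cells.  For each cell and platform, a unit vector at the cell's circular
    mean allocentric spike head direction on that platform is scaled by the
    platform-associated mean firing rate (spikes / occupancy seconds) times
    the cell's MRL; vectors are summed across the cells that fired spikes on
    the platform.
    """
    if len(cells) == 0:
        raise ValueError("need at least one ConSink cell")
    P = maze.n_platforms
    occ = np.bincount(
        tracking.platform[tracking.platform >= 0], minlength=P
    ).astype(float) * tracking.dt
    vec = np.zeros((P, 2))
    n_spk = np.zeros(P)
    for spikes, mrl in cells:
        on = spikes.platform >= 0
        plat = spikes.platform[on]
        ang = np.deg2rad(spikes.head_dir[on])
        counts = np.bincount(plat, minlength=P).astype(float)
        zc = np.bincount(plat, weights=np.cos(ang), minlength=P)
        zs = np.bincount(plat, weights=np.sin(ang), minlength=P)
        theta = np.arctan2(zs, zc)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(occ > 0, counts / np.maximum(occ, 1e-300), 0.0)
        fired = counts > 0
        w = rate * mrl
        vec[fired, 0] += w[fired] * np.cos(theta[fired])
        vec[fired, 1] += w[fired] * np.sin(theta[fired])
        n_spk += counts
    length = np.hypot(vec[:, 0], vec[:, 1])
    direction = np.rad2deg(np.arctan2(vec[:, 1], vec[:, 0])) % 360.0
    direction[length <= 1e-12] = np.nan
    return VectorField(
        positions=maze.centers.copy(),
        direction=direction,
        length=length,
        n_spikes=n_spk,
    )


def population_sink(field: VectorField, grid: SinkGrid, n_bins: int = 24) -> PopulationSink:
    """Candidate position maximising the length-weighted MRL of platform
    vector directions expressed relative to the candidate."""
    ok = np.isfinite(field.direction) & (field.length > 0)
    if not np.any(ok):
        raise ValueError("vector field has no defined platform vectors")
    px, py = field.positions[ok, 0], field.positions[ok, 1]
    d = field.direction[ok]
    wgt = field.length[ok]
    cand = grid.candidates
    brg = np.rad2deg(np.arctan2(cand[:, 1, None] - py, cand[:, 0, None] - px))
    idx = _bin_of(d[None, :] - brg, n_bins)
    C = grid.n_candidates
    flat = (idx + np.arange(C)[:, None] * n_bins).ravel()
    hist = np.bincount(
        flat, weights=np.broadcast_to(wgt, idx.shape).ravel(), minlength=C * n_bins
    ).reshape(C, n_bins)
    theta = np.deg2rad(bin_centers(n_bins))
    z = hist @ np.exp(1j * theta)
    tot = hist.sum(axis=1)
    mrl = np.abs(z) / tot
    best = int(np.argmax(mrl))
    iy, ix = divmod(best, grid.nx)
    return PopulationSink(
        sink_xy=(float(grid.x[ix]), float(grid.y[iy])),
        mrl=float(mrl[best]),
        mrl_map=mrl.reshape(grid.ny, grid.nx),
        preferred_rd=float(wrap_180(np.rad2deg(np.angle(z[best])))),
    )
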