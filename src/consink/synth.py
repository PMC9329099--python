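"""Seeded generation of complete synthetic honeycomb-maze sessions.

A session consists of (i) a task event stream (trials of binary platform
choices converging on a goal), (ii) a ~25 Hz tracking series in which the
animal dwells on the occupied platform and scans the full range of headings
(as rats do on the real maze), and (iii) per-cell spike trains drawn from an
inhomogeneous Poisson rate model with known ground truth.

Cell classes
------------
``consink``    von Mises tuning to the egocentric bearing toward a fixed
               sink point, optionally multiplied by a Gaussian place field
               and by distance-to-sink / allocentric-direction gains.
``place_only`` Gaussian place field, no directional tuning.
``allo_hd``    von Mises tuning to allocentric head direction.
``uniform``    homogeneous Poisson.

The rate is normalised so the session-mean rate equals ``base_rate``;
spikes are drawn by thinning with the rate held constant within each video
frame (exact for a piecewise-constant rate).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._circ import wrap_360
from .geometry import MazeGeometry, bearing, build_honeycomb

__all__ = [
    "Tracking",
    "Subtrial",
    "TaskEvents",
    "CellTruth",
    "Session",
    "ScanParams",
    "TaskTiming",
    "generate_task",
    "generate_trajectory",
    "generate_forage_tracking",
    "generate_spikes",
    "generate_spikes_time_rescaling",
    "generate_session",
    "make_cells",
]

NECK_CM = 5.0  # head marker sits this far in front of the torso marker


def as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class Tracking:
    """Time-indexed pose: head position/direction, torso position, platform."""

    t: np.ndarray
    head_xy: np.ndarray  # (n, 2)
    head_dir: np.ndarray  # degrees [0, 360)
    torso_xy: np.ndarray  # (n, 2)
    platform: np.ndarray  # platform id per frame, -1 off-maze

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.head_xy = np.asarray(self.head_xy, float)
        self.head_dir = np.asarray(self.head_dir, float)
        self.torso_xy = np.asarray(self.torso_xy, float)
        self.platform = np.asarray(self.platform, int)

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "head_x": self.head_xy[:, 0],
                "head_y": self.head_xy[:, 1],
                "head_dir": self.head_dir,
                "torso_x": self.torso_xy[:, 0],
                "torso_y": self.torso_xy[:, 1],
                "platform": self.platform,
            }
        )

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, maze: MazeGeometry | None = None):
        torso = df[["torso_x", "torso_y"]].to_numpy()
        if "platform" in df.columns:
            plat = df["platform"].to_numpy(int)
        elif maze is not None:
            plat = maze.platform_of(torso)
        else:
            raise ValueError("need a platform column or a maze to assign one")
        return cls(
            t=df["t"].to_numpy(),
            head_xy=df[["head_x", "head_y"]].to_numpy(),
            head_dir=df["head_dir"].to_numpy(),
            torso_xy=torso,
            platform=plat,
        )

    @classmethod
    def from_csv(cls, path, maze: MazeGeometry | None = None):
        return cls.from_frame(pd.read_csv(path), maze)


@dataclass
class Subtrial:
    trial: int
    index: int
    start_platform: int
    pair: tuple
    chosen: int
    correct: bool | None  # None = unscored (equidistant pair)
    t_start: float
    t_offer: float
    t_choice: float
    wait1: tuple  # (t0, t1), 4 s
    wait2: tuple  # (t0, t1), 4 s ending 1 s before the transition


@dataclass
class TaskEvents:
    subtrials: list
    goal: int
    epoch: str = "goal1"
    t_start: float = 0.0
    t_end: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subtrials:
            rows.append(
                {
                    "trial": s.trial,
                    "subtrial": s.index,
                    "platform_from": s.start_platform,
                    "pair_a": s.pair[0],
                    "pair_b": s.pair[1],
                    "chosen": s.chosen,
                    "correct": "" if s.correct is None else int(s.correct),
                    "t_offer": s.t_offer,
                    "t_choice": s.t_choice,
                    "wait1_t0": s.wait1[0],
                    "wait1_t1": s.wait1[1],
                    "wait2_t0": s.wait2[0],
                    "wait2_t1": s.wait2[1],
                    "epoch": self.epoch,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def wait_windows(self, which: int, correct: bool | None = None) -> list:
        """(t0, t1) windows for wait period 1 or 2, optionally filtered by
        choice outcome."""
        out = []
        for s in self.subtrials:
            if correct is not None and s.correct is not correct:
                continue
            out.append(s.wait1 if which == 1 else s.wait2)
        return out


@dataclass
class CellTruth:
    """Ground-truth generative parameters for one simulated cell."""

    cell_id: str
    cell_class: str  # consink | place_only | allo_hd | uniform
    base_rate: float = 2.0  # Hz, session-mean rate
    sink_xy: tuple | None = None
    mu_rd: float = 0.0  # preferred relative direction, degrees
    kappa_rd: float = 0.0
    field_center: tuple | None = None
    field_sigma: float | None = None  # cm
    ds_pref: float | None = None  # preferred distance to sink, cm
    ds_width: float | None = None  # cm
    ds_gain: float = 0.0  # log-amplitude of the distance gain
    mu_ad: float = 0.0  # preferred allocentric direction, degrees
    kappa_ad: float = 0.0
    error_gain: float = 1.0  # rate multiplier inside error wait windows

    def __post_init__(self):
        if self.kappa_rd < 0 or self.kappa_ad < 0:
            raise ValueError("concentration parameters must be >= 0")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("sink_xy", "field_center"):
            if d[k] is not None:
                d[k] = [float(v) for v in d[k]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CellTruth":
        d = dict(d)
        for k in ("sink_xy", "field_center"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class TaskTiming:
    """Timing of one subtrial; values loosely follow the real task's pacing
    (4-s waits, 4-10-s raise delay, a second or two per platform crossing)."""

    wait1: float = 4.0
    raise_delay: tuple = (2.0, 3.0)
    scan: tuple = (5.5, 7.5)
    transition: float = 1.0
    reward: float = 8.0
    carry: float = 3.0


@dataclass
class ScanParams:
    """Platform-confined scanning behaviour.

    The default heading model is a triangle-wave sweep (amplitude
    ``sweep_amplitude`` degrees, period ``sweep_period`` s) around a random
    base direction per dwell, guaranteeing >=180 degrees of sweep within any
    4-s wait window and full coverage of all 24 relative-direction bins over
    a session.  Setting ``heading_bias_point`` switches to a biased mode in
    which the heading is an Ornstein-Uhlenbeck excursion (stationary s.d.
    ``heading_bias_sigma_deg``) around the bearing to that point —
    deliberately uneven directional sampling for testing the occupancy
    correction.
    """

    sweep_amplitude: float = 300.0
    sweep_period: float = 3.0
    heading_noise_deg: float = 8.0
    heading_bias_point: tuple | None = None
    heading_bias_sigma_deg: float = 55.0
    torso_radius_frac: float = 0.35  # of the platform apothem
    torso_omega: tuple = (0.3, 0.6)  # rad/s drift around the platform centre


@dataclass
class Session:
    maze: MazeGeometry
    task: TaskEvents
    tracking: Tracking
    cells: list
    spikes: dict  # cell_id -> spike-time array
    seed: int | None = None

    def spike_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame({"cell_id": cid, "t": np.asarray(ts)})
            for cid, ts in self.spikes.items()
        ]
        return pd.concat(rows, ignore_index=True)

    def save(self, outdir):
        import os

        os.makedirs(outdir, exist_ok=True)
        self.maze.to_json(os.path.join(outdir, "maze.json"))
        self.tracking.to_csv(os.path.join(outdir, "tracking.csv"))
        self.task.to_csv(os.path.join(outdir, "events.csv"))
        self.spike_frame().to_csv(os.path.join(outdir, "spikes.csv"), index=False)
        truth = {
            "seed": self.seed,
            "goal": self.task.goal,
            "epoch": self.task.epoch,
            "cells": [c.to_dict() for c in self.cells],
        }
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1)

    @classmethod
    def load(cls, outdir):
        import os

        maze = MazeGeometry.from_json(os.path.join(outdir, "maze.json"))
        tracking = Tracking.from_csv(os.path.join(outdir, "tracking.csv"), maze)
        with open(os.path.join(outdir, "truth.json")) as fh:
            truth = json.load(fh)
        cells = [CellTruth.from_dict(c) for c in truth["cells"]]
        sp = pd.read_csv(os.path.join(outdir, "spikes.csv"))
        spikes = {
            cid: g["t"].to_numpy() for cid, g in sp.groupby("cell_id", sort=False)
        }
        ev = pd.read_csv(os.path.join(outdir, "events.csv"))
        subtrials = [
            Subtrial(
                trial=int(r.trial),
                index=int(r.subtrial),
                start_platform=int(r.platform_from),
                pair=(int(r.pair_a), int(r.pair_b)),
                chosen=int(r.chosen),
                correct=None if pd.isna(r.correct) else bool(int(r.correct)),
                t_start=float(r.wait1_t0),
                t_offer=float(r.t_offer),
                t_choice=float(r.t_choice),
                wait1=(float(r.wait1_t0), float(r.wait1_t1)),
                wait2=(float(r.wait2_t0), float(r.wait2_t1)),
            )
            for r in ev.itertuples()
        ]
        task = TaskEvents(
            subtrials,
            goal=truth["goal"],
            epoch=truth.get("epoch", "goal1"),
            t_start=float(tracking.t[0]),
            t_end=float(tracking.t[-1]),
        )
        return cls(maze, task, tracking, cells, spikes, seed=truth.get("seed"))


# ---------------------------------------------------------------------------
# task generation
# ---------------------------------------------------------------------------
def _subsections(maze: MazeGeometry, n: int = 13) -> list:
    """Partition platforms into *n* angular subsections around the maze
    centre (the centre platform joins the first subsection)."""
    ang = np.arctan2(maze.centers[:, 1], maze.centers[:, 0]) % (2 * np.pi)
    sec = np.minimum((ang / (2 * np.pi) * n).astype(int), n - 1)
    r = np.hypot(maze.centers[:, 0], maze.centers[:, 1])
    sec[r < 1e-9] = 0
    return [np.flatnonzero(sec == k) for k in range(n)]


def generate_task(
    maze: MazeGeometry,
    n_trials: int,
    seed,
    p_correct: float = 0.85,
    epoch: str = "goal1",
    t_start: float = 0.0,
    timing: TaskTiming | None = None,
    prefer_unused: bool = True,
) -> TaskEvents:
    """Generate a task event stream of *n_trials* trials to the maze goal.

    Each trial starts on a platform drawn from one of 13 maze subsections;
    choice pairs are two platforms adjacent to the occupied one such that at
    least one is strictly closer to the goal, with previously unused
    platforms preferred where possible.  The simulated animal chooses the
    closer platform with probability ``p_correct``; equidistant pairs are
    left unscored.
    """
    if maze.goal is None:
        raise ValueError("maze.goal must be set before generating a task")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    timing = timing or TaskTiming()
    goal_xy = maze.centers[maze.goal]
    dist = np.linalg.norm(maze.centers - goal_xy, axis=1)
    sections = _subsections(maze)
    starts = []
    for k in range(n_trials):
        sec = sections[k % len(sections)]
        sec = sec[sec != maze.goal]
        if len(sec) == 0:
            sec = np.array([i for i in range(maze.n_platforms) if i != maze.goal])
        starts.append(int(rng.choice(sec)))

    subtrials = []
    used = set()
    t = t_start
    for trial, start in enumerate(starts):
        current = start
        used.add(current)
        index = 0
        while current != maze.goal:
            nbrs = maze.neighbours(current)
            pairs = [
                (a, b)
                for i, a in enumerate(nbrs)
                for b in nbrs[i + 1 :]
                if min(dist[a], dist[b]) < dist[current] - 1e-9
            ]
            n_new = [int(a not in used) + int(b not in used) for a, b in pairs]
            best = max(n_new) if prefer_unused else None
            candidates = (
                [p for p, k in zip(pairs, n_new) if k == best]
                if prefer_unused
                else pairs
            )
            pair = candidates[rng.integers(len(candidates))]
            used.update(pair)

            da, db = dist[pair[0]], dist[pair[1]]
            if abs(da - db) < 1e-9:
                chosen = pair[rng.integers(2)]
                correct = None
            else:
                closer = pair[0] if da < db else pair[1]
                other = pair[1] if da < db else pair[0]
                chosen = closer if rng.random() < p_correct else other
                correct = chosen == closer

            t0 = t
            t_offer = t0 + timing.wait1 + rng.uniform(*timing.raise_delay)
            t_choice = t_offer + rng.uniform(*timing.scan)
            sub = Subtrial(
                trial=trial,
                index=index,
                start_platform=current,
                pair=pair,
                chosen=int(chosen),
                correct=correct,
                t_start=t0,
                t_offer=t_offer,
                t_choice=t_choice,
                wait1=(t0, t0 + timing.wait1),
                wait2=(t_choice - 5.0, t_choice - 1.0),
            )
            subtrials.append(sub)
            current = int(chosen)
            t = t_choice + timing.transition
            index += 1
        t += timing.reward  # reward consumption on the goal platform
        t += timing.carry  # carried to the next start platform
    return TaskEvents(subtrials, goal=maze.goal, epoch=epoch, t_start=t_start, t_end=t)


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------
def _segments_from_task(task: TaskEvents, maze: MazeGeometry, timing: TaskTiming):
    """Dwell/move segment list covering the whole task timeline."""
    segs = []
    t_cursor = task.t_start
    prev_platform = None
    for s in task.subtrials:
        if s.index == 0 and prev_platform is not None:
            # carried from the previous goal to this trial's start platform
            segs.append(("move", prev_platform, s.start_platform, t_cursor, s.t_start))
        segs.append(("dwell", s.start_platform, None, s.t_start, s.t_choice))
        segs.append(
            ("move", s.start_platform, s.chosen, s.t_choice, s.t_choice + timing.transition)
        )
        t_cursor = s.t_choice + timing.transition
        prev_platform = s.chosen
        if s.chosen == task.goal:
            segs.append(("dwell", task.goal, None, t_cursor, t_cursor + timing.reward))
            t_cursor += timing.reward
    if t_cursor < task.t_end:
        segs.append(("dwell", prev_platform, None, t_cursor, task.t_end))
    return segs


def _trajectory_from_segments(
    segs, maze: MazeGeometry, scan: ScanParams, rng, fs: float
) -> Tracking:
    t_end = segs[-1][4]
    t = np.arange(segs[0][3], t_end, 1.0 / fs)
    n = len(t)
    torso = np.zeros((n, 2))
    hd = np.zeros(n)

    biased = scan.heading_bias_point is not None
    if biased:
        # one continuous OU excursion process across the session
        tau, dt = 0.5, 1.0 / fs
        a = np.exp(-dt / tau)
        sd = scan.heading_bias_sigma_deg
        eps = rng.normal(0.0, sd * np.sqrt(1 - a**2), size=n)
        z = np.empty(n)
        z[0] = rng.normal(0.0, sd)
        for k in range(1, n):
            z[k] = a * z[k - 1] + eps[k]

    for kind, p_from, p_to, t0, t1 in segs:
        m = (t >= t0 - 1e-9) & (t < t1 - 1e-9)
        if not np.any(m):
            continue
        tt = t[m] - t0
        if kind == "dwell":
            c = maze.centers[p_from]
            r = scan.torso_radius_frac * maze.apothem
            omega = rng.uniform(*scan.torso_omega) * rng.choice([-1.0, 1.0])
            phi = rng.uniform(0, 2 * np.pi) + omega * tt
            torso[m, 0] = c[0] + r * np.cos(phi)
            torso[m, 1] = c[1] + r * np.sin(phi)
            if not biased:
                base = rng.uniform(0.0, 360.0)
                ph = rng.uniform(0.0, scan.sweep_period)
                x = ((tt + ph) / scan.sweep_period) % 1.0
                tri = np.where(x < 0.5, 2 * x - 0.5, 1.5 - 2 * x)  # [-0.5, 0.5]
                noise = rng.normal(0.0, scan.heading_noise_deg, size=tt.size)
                hd[m] = base + scan.sweep_amplitude * tri + noise
        else:  # move
            c0, c1 = maze.centers[p_from], maze.centers[p_to]
            frac = (tt / max(t1 - t0, 1e-9))[:, None]
            torso[m] = c0 + frac * (c1 - c0)
            if not biased:
                hd[m] = bearing(c0, c1) + rng.normal(
                    0.0, scan.heading_noise_deg, size=tt.size
                )

    if biased:
        target = np.asarray(scan.heading_bias_point, float)
        hd = bearing(torso, target) + z
    hd = wrap_360(hd)
    u = np.stack([np.cos(np.deg2rad(hd)), np.sin(np.deg2rad(hd))], axis=1)
    head = torso + NECK_CM * u
    platform = maze.platform_of(torso)
    return Tracking(t=t, head_xy=head, head_dir=hd, torso_xy=torso, platform=platform)


def generate_trajectory(
    task: TaskEvents,
    maze: MazeGeometry,
    scan: ScanParams | None = None,
    seed=0,
    fs: float = 25.0,
    timing: TaskTiming | None = None,
) -> Tracking:
    """Synthesize a ~25 Hz tracking series for a task event stream."""
    rng = np.random.default_rng(seed)
    segs = _segments_from_task(task, maze, timing or TaskTiming())
    return _trajectory_from_segments(segs, maze, scan or ScanParams(), rng, fs)


def generate_forage_tracking(
    maze: MazeGeometry,
    duration: float,
    seed=0,
    scan: ScanParams | None = None,
    fs: float = 25.0,
) -> Tracking:
    """Open-field-foraging analogue: a random walk over adjacent platforms
    with the same scanning behaviour as during the task."""
    rng = np.random.default_rng(seed)
    segs = []
    t = 0.0
    current = int(rng.integers(maze.n_platforms))
    while t < duration:
        dwell = rng.uniform(3.0, 6.0)
        segs.append(("dwell", current, None, t, t + dwell))
        t += dwell
        nxt = int(rng.choice(maze.neighbours(current)))
        segs.append(("move", current, nxt, t, t + 1.0))
        t += 1.0
        current = nxt
    return _trajectory_from_segments(segs, maze, scan or ScanParams(), rng, fs)


# ---------------------------------------------------------------------------
# spike generation
# ---------------------------------------------------------------------------
def _frame_rate(cell: CellTruth, tracking: Tracking) -> np.ndarray:
    """Per-frame rate (Hz), normalised so the session mean equals base_rate."""
    n = tracking.n_frames
    if n == 0:
        raise ValueError("empty tracking")
    log_u = np.zeros(n)
    pos = tracking.head_xy
    if cell.cell_class in ("consink",):
        sink = np.asarray(cell.sink_xy, float)
        d = sink - pos
        brg = np.rad2deg(np.arctan2(d[:, 1], d[:, 0]))
        rd = np.deg2rad(tracking.head_dir - brg)
        log_u += cell.kappa_rd * np.cos(rd - np.deg2rad(cell.mu_rd))
        if cell.ds_gain:
            dist = np.hypot(d[:, 0], d[:, 1])
            log_u += cell.ds_gain * np.exp(
                -((dist - cell.ds_pref) ** 2) / (2 * cell.ds_width**2)
            )
        if cell.kappa_ad:
            log_u += cell.kappa_ad * np.cos(np.deg2rad(brg - cell.mu_ad))
    if cell.cell_class == "allo_hd":
        log_u += cell.kappa_ad * np.cos(
            np.deg2rad(tracking.head_dir - cell.mu_ad)
        )
    if cell.field_sigma is not None and cell.cell_class in ("consink", "place_only"):
        fc = np.asarray(cell.field_center, float)
        d2 = np.sum((pos - fc) ** 2, axis=1)
        log_u += -d2 / (2 * cell.field_sigma**2)
    u = np.exp(log_u - log_u.max())
    return cell.base_rate * u / u.mean()


def _apply_rate_windows(lam, t, rate_windows):
    if rate_windows:
        lam = lam.copy()
        for t0, t1, gain in rate_windows:
            lam[(t >= t0) & (t < t1)] *= gain
    return lam


def generate_spikes(
    cell: CellTruth,
    tracking: Tracking,
    seed,
    rate_windows: list | None = None,
) -> np.ndarray:
    """Sample spike times by thinning an inhomogeneous Poisson process whose
    rate is held constant within each tracking frame."""
    rng = np.random.default_rng(seed)
    lam = _apply_rate_windows(_frame_rate(cell, tracking), tracking.t, rate_windows)
    t0, t1 = tracking.t[0], tracking.t[-1]
    lam_max = float(lam.max())
    n_prop = rng.poisson(lam_max * (t1 - t0))
    tt = np.sort(rng.uniform(t0, t1, size=n_prop))
    idx = np.clip(np.searchsorted(tracking.t, tt, side="right") - 1, 0, len(lam) - 1)
    keep = rng.uniform(0.0, lam_max, size=n_prop) < lam[idx]
    return tt[keep]


def generate_spikes_time_rescaling(
    cell: CellTruth,
    tracking: Tracking,
    seed,
    rate_windows: list | None = None,
) -> np.ndarray:
    """Alternative exact sampler via the time-rescaling theorem (used as an
    independent distributional cross-check of the thinning sampler)."""
    rng = np.random.default_rng(seed)
    lam = _apply_rate_windows(_frame_rate(cell, tracking), tracking.t, rate_windows)
    dt = tracking.dt
    cum = np.concatenate([[0.0], np.cumsum(lam * dt)])
    edges = np.concatenate([tracking.t, [tracking.t[-1] + dt]])
    total = cum[-1]
    out, s = [], 0.0
    while True:
        s += rng.exponential(1.0)
        if s >= total:
            break
        out.append(np.interp(s, cum, edges))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# populations and whole sessions
# ---------------------------------------------------------------------------
def make_cells(
    rng,
    maze: MazeGeometry,
    n: int,
    cell_class: str,
    prefix: str | None = None,
    base_rate=(1.5, 2.5),
    kappa_rd=(2.0, 2.0),
    mu_rd_sd: float = 0.0,
    sink_center=None,
    sink_sd: float | None = None,
    field_sigma: float | str | None = "default",
    ds_gain: float = 0.0,
    ds_width: float = 30.0,
    kappa_ad: float = 0.0,
    error_gain: float = 1.0,
) -> list:
    """Draw *n* cells of one class with randomized parameters.

    Sinks default to random platform centres with jitter ("across the
    maze"); pass ``sink_center``/``sink_sd`` for a goal-clustered population.
    Field centres are random platform centres.  The base ConSink phenotype
    is purely direction-tuned (no place field) unless ``field_sigma`` is
    given; place-only cells default to a 40-cm field.
    """
    prefix = prefix or cell_class
    if field_sigma == "default":
        field_sigma = 40.0 if cell_class == "place_only" else None
    cells = []
    for k in range(n):
        sink = None
        if cell_class == "consink":
            if sink_center is not None:
                sd = 8.0 if sink_sd is None else sink_sd
                sink = tuple(np.asarray(sink_center, float) + rng.normal(0, sd, 2))
            else:
                pid = int(rng.integers(maze.n_platforms))
                sink = tuple(maze.centers[pid] + rng.uniform(-4, 4, 2))
        fc = None
        if field_sigma is not None and cell_class in ("consink", "place_only"):
            fc = tuple(maze.centers[int(rng.integers(maze.n_platforms))])
        ds_pref = None
        if ds_gain:
            ds_pref = float(rng.uniform(20.0, 80.0))
        cells.append(
            CellTruth(
                cell_id=f"{prefix}_{k:03d}",
                cell_class=cell_class,
                base_rate=float(rng.uniform(*base_rate)),
                sink_xy=sink,
                mu_rd=float(rng.normal(0.0, mu_rd_sd)),
                kappa_rd=float(rng.uniform(*kappa_rd)) if cell_class == "consink" else 0.0,
                field_center=fc,
                field_sigma=field_sigma if fc is not None else None,
                ds_pref=ds_pref,
                ds_width=ds_width if ds_gain else None,
                ds_gain=ds_gain,
                mu_ad=float(rng.uniform(0.0, 360.0)),
                kappa_ad=kappa_ad,
                error_gain=error_gain,
            )
        )
    return cells


def generate_session(
    cells: list,
    seed,
    maze: MazeGeometry | None = None,
    n_trials: int = 13,
    p_correct: float = 0.85,
    scan: ScanParams | None = None,
    epoch: str = "goal1",
    fs: float = 25.0,
    tracking: Tracking | None = None,
    task: TaskEvents | None = None,
    duration: float | None = None,
) -> Session:
    """Generate a full session: task, trajectory and one spike train per
    cell.  All randomness flows from *seed* via named substreams, so equal
    seeds give bit-identical sessions.  A pre-built task/tracking pair may
    be passed to reuse one trajectory across cell populations.  If
    *duration* is given, trials are generated until the timeline covers it
    and the tracking is trimmed to exactly that length.
    """
    if maze is None:
        maze = build_honeycomb(goal=45)
    ids = [c.cell_id for c in cells]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell_id values in the cell list")
    ss = as_seed_sequence(seed)
    s_task, s_traj, s_cells = ss.spawn(3)
    if task is None:
        task = generate_task(maze, n_trials, s_task, p_correct=p_correct, epoch=epoch)
        while duration is not None and task.t_end < duration:
            task = generate_task(
                maze, n_trials + 5, s_task, p_correct=p_correct, epoch=epoch
            )
            n_trials += 5
    if tracking is None:
        tracking = generate_trajectory(task, maze, scan=scan, seed=s_traj, fs=fs)
    if duration is not None and tracking.duration > duration:
        keep = tracking.t - tracking.t[0] < duration
        tracking = Tracking(
            tracking.t[keep], tracking.head_xy[keep], tracking.head_dir[keep],
            tracking.torso_xy[keep], tracking.platform[keep],
        )
        task = TaskEvents(
            [s for s in task.subtrials if s.t_choice <= tracking.t[-1]],
            goal=task.goal, epoch=task.epoch,
            t_start=task.t_start, t_end=float(tracking.t[-1]),
        )
    err_w1 = task.wait_windows(1, correct=False)
    err_w2 = task.wait_windows(2, correct=False)
    spikes = {}
    for cell, sub in zip(cells, s_cells.spawn(len(cells))):
        windows = None
        if cell.error_gain != 1.0:
            windows = [(t0, t1, cell.error_gain) for t0, t1 in err_w1 + err_w2]
        spikes[cell.cell_id] = generate_spikes(cell, tracking, sub, windows)
    return Session(maze, task, tracking, cells, spikes, seed=seed)
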