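"""End-to-end orchestration: configuration, seeding, stage execution and
JSON/CSV output with provenance (config hash + seed in every artifact)."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import fields as fields_mod
from . import goalstats, lnmodel, prep, sinks, synth
from .geometry import build_honeycomb

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All tunables of a run; defaults follow the analysis conventions used
    throughout the package (24 RD bins, 7-cm sink grid, 100-ms LN windows,
    4-s waits, 500-spike inclusion rule, alpha = 0.05)."""

    seed: int = 0
    outdir: str = "results/run"
    # simulation
    n_cells_consink: int = 8
    n_cells_place: int = 2
    n_cells_allo: int = 2
    n_trials: int = 13
    goal_platform: int = 45
    p_correct: float = 0.85
    # analysis
    grid_nx: int = 34
    grid_ny: int = 29
    grid_spacing: float = 7.0
    n_shuffles: int = 1000
    n_shifts: int = 1000
    min_shift: float = 60.0
    rd_bins: int = 24
    ln_bins: dict = field(default_factory=lambda: dict(lnmodel.DEFAULT_BINS))
    ln_window: float = 0.1
    ln_beta: float = 1.0
    min_spikes: int = 500
    alpha: float = 0.05
    goalward_tol: float = 15.0
    screen_shifts: int = 200
    do_bursts: bool = True
    run_ln: bool = True

    def validate(self):
        if self.n_shuffles < 20 or self.n_shifts < 20:
            raise ValueError("n_shuffles/n_shifts must be at least 20")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)


def _provenanced(cfg: RunConfig, payload: dict) -> dict:
    return {"config_hash": cfg.hash, "seed": cfg.seed, **payload}


def _dump(cfg: RunConfig, name: str, payload: dict):
    os.makedirs(cfg.outdir, exist_ok=True)
    path = os.path.join(cfg.outdir, name)
    if os.path.exists(path):
        with open(path) as fh:
            try:
                existing = json.load(fh)
            except json.JSONDecodeError:
                existing = None
        if existing is not None and existing.get("config_hash") != cfg.hash:
            raise FileExistsError(
                f"{path} was produced by a different configuration; refusing to overwrite"
            )
    with open(path, "w") as fh:
        json.dump(_provenanced(cfg, payload), fh, indent=1, sort_keys=True)


def simulate_stage(cfg: RunConfig) -> synth.Session:
    maze = build_honeycomb(goal=cfg.goal_platform)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    cells = (
        synth.make_cells(rng, maze, cfg.n_cells_consink, "consink",
                         sink_center=maze.centers[maze.goal], sink_sd=12.0)
        + synth.make_cells(rng, maze, cfg.n_cells_place, "place_only")
        + synth.make_cells(rng, maze, cfg.n_cells_allo, "allo_hd", kappa_ad=2.0,
                           field_sigma=None)
    )
    return synth.generate_session(
        cells,
        seed=int(np.random.SeedSequence([cfg.seed, 2]).generate_state(1)[0]),
        maze=maze,
        n_trials=cfg.n_trials,
        p_correct=cfg.p_correct,
    )


def run_pipeline(cfg: RunConfig, session: synth.Session | None = None) -> dict:
    """Execute simulate -> screen -> detect -> fields -> ln -> goalstats and
    write JSON results under ``cfg.outdir``.  Returns the result bundle."""
    cfg.validate()
    if session is None:
        session = simulate_stage(cfg)
        session.save(os.path.join(cfg.outdir, "session"))
    maze, tracking, task = session.maze, session.tracking, session.task

    posed = {
        cid: prep.interpolate_pose(ts, tracking, cid, maze)
        for cid, ts in session.spikes.items()
    }
    screened = {
        cid: sp for cid, sp in posed.items() if sp.n >= cfg.min_spikes
    }
    log = {
        "n_cells": len(posed),
        "n_screened": len(screened),
    }

    grid = sinks.make_sink_grid(
        tracking, nx=cfg.grid_nx, ny=cfg.grid_ny, spacing=cfg.grid_spacing
    )
    ctx = sinks.SinkSearchContext(tracking, grid, n_bins=cfg.rd_bins)
    results = {}
    for k, (cid, sp) in enumerate(sorted(screened.items())):
        results[cid] = sinks.detect_consink(
            sp, tracking, grid, maze,
            n_shuffles=cfg.n_shuffles, n_shifts=cfg.n_shifts,
            min_shift=cfg.min_shift, alpha=cfg.alpha,
            seed=np.random.SeedSequence([cfg.seed, 3, k]), ctx=ctx,
            do_bursts=cfg.do_bursts,
        )
    sig = {cid: r for cid, r in results.items() if r.significant}
    log["n_significant"] = len(sig)
    _dump(cfg, "consinks.json", {"cells": {c: r.to_dict() for c, r in results.items()}})

    bundle = {"session": session, "results": results, "log": log, "grid": grid}
    if sig:
        pvf = fields_mod.population_vector_field(
            [(screened[cid], r.mrl) for cid, r in sig.items()], tracking, maze
        )
        psink = fields_mod.population_sink(pvf, grid)
        _dump(cfg, "population.json", {
            "population_sink": list(psink.sink_xy),
            "population_mrl": psink.mrl,
            "goal_xy": list(maze.centers[maze.goal]),
        })
        bundle["population_sink"] = psink

        if cfg.run_ln:
            ln = {}
            for cid, r in sig.items():
                ln[cid] = lnmodel.run_ln_analysis(
                    screened[cid], tracking, r.sink_xy,
                    beta=cfg.ln_beta, window=cfg.ln_window,
                )
            log["ln_selected"] = {c: v.selected for c, v in ln.items()}
            _dump(cfg, "ln.json", {"cells": {c: v.to_dict() for c, v in ln.items()}})
            bundle["ln"] = ln

        goal_xy = maze.centers[maze.goal]
        ft = goalstats.fantail([screened[cid] for cid in sig], tracking, goal_xy)
        cells_ce = [
            {"spikes": screened[cid], "sink": r.sink_xy, "preferred_rd": r.preferred_rd}
            for cid, r in sig.items()
        ]
        ce = goalstats.compare_correct_error(
            cells_ce, task, tracking, goal_xy, tol=cfg.goalward_tol
        )
        beh = goalstats.behavioural_score(task)
        _dump(cfg, "goalstats.json", {
            "fantail_bin_centers": list(map(float, ft.bin_centers)),
            "fantail_rate": [None if not np.isfinite(v) else float(v) for v in ft.rate],
            "behaviour": beh,
            "correct_error": {
                k: {
                    kk: vv
                    for kk, vv in v.items()
                    if isinstance(vv, (int, float, bool))
                }
                for k, v in ce.items()
            },
        })
        bundle["fantail"] = ft
        bundle["correct_error"] = ce
        bundle["behaviour"] = beh
    _dump(cfg, "log.json", log)
    return bundle
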