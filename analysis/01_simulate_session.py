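#!/usr/bin/env python
"""Simulate a honeycomb-maze recording session and write it to disk.

Generates a 13-trial navigation session with a mixed cell population
(goal-clustered ConSink cells, place-only cells, an allocentric HD cell and
a homogeneous cell), saves tracking/spikes/events/ground truth under
results/session/, and prints the behavioural summary.
"""
import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from consink import goalstats, synth  # noqa: E402
from consink.geometry import build_honeycomb  # noqa: E402

SEED = 2026
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "session")


def main():
    maze = build_honeycomb(goal=45)
    goal_xy = maze.centers[maze.goal]
    rng = np.random.default_rng(SEED)
    cells = (
        synth.make_cells(rng, maze, 10, "consink", sink_center=goal_xy,
                         sink_sd=10.0, mu_rd_sd=10.0, kappa_rd=(1.5, 3.0),
                         base_rate=(1.5, 2.5))
        + synth.make_cells(rng, maze, 3, "place_only", base_rate=(1.5, 2.5))
        + synth.make_cells(rng, maze, 1, "allo_hd", kappa_ad=2.5,
                           base_rate=(1.5, 2.5), field_sigma=None)
        + synth.make_cells(rng, maze, 1, "uniform", base_rate=(1.5, 2.5),
                           field_sigma=None)
    )
    ses = synth.generate_session(cells, seed=SEED, maze=maze, n_trials=13)
    ses.save(OUT)
    beh = goalstats.behavioural_score(ses.task)
    print(f"session: {ses.tracking.duration:.0f} s, "
          f"{len(ses.task.subtrials)} subtrials, {len(cells)} cells")
    print(f"behaviour: {beh['n_correct']}/{beh['n_scored']} correct choices, "
          f"binomial p = {beh['binomial_p']:.2e}")
    print(f"wrote {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
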