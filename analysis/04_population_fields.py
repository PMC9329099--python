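#!/usr/bin/env python
"""Population vector field and population ConSink.

Takes the cells flagged significant by 03_detect_consinks.py, builds the
platform-level population vector field (unit vectors at each cell's mean
platform heading, scaled by platform rate x MRL, summed across cells),
localises the population sink, and writes results/population_field.csv plus
a quiver plot.
"""
import os
import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from consink import fields, prep, sinks, synth  # noqa: E402

HERE = os.path.dirname(__file__)
SESSION = os.path.join(HERE, "..", "results", "session")
CONSINKS = os.path.join(HERE, "..", "results", "consinks.csv")
OUT = os.path.join(HERE, "..", "results", "population_field.csv")
FIG = os.path.join(HERE, "..", "results", "population_field.png")


def main():
    ses = synth.Session.load(SESSION)
    det = pd.read_csv(CONSINKS)
    sig = det[det["significant"]]
    pairs = []
    for row in sig.itertuples():
        sp = prep.interpolate_pose(ses.spikes[row.cell_id], ses.tracking,
                                   row.cell_id, ses.maze)
        pairs.append((sp, float(row.mrl)))
    pvf = fields.population_vector_field(pairs, ses.tracking, ses.maze)
    grid = sinks.make_sink_grid(ses.tracking)
    ps = fields.population_sink(pvf, grid)
    goal_xy = ses.maze.centers[ses.maze.goal]
    dist = np.linalg.norm(np.asarray(ps.sink_xy) - goal_xy)

    pd.DataFrame({
        "platform": np.arange(ses.maze.n_platforms),
        "direction_deg": pvf.direction,
        "vector_length": pvf.length,
        "n_spikes": pvf.n_spikes,
    }).to_csv(OUT, index=False)

    ok = np.isfinite(pvf.direction)
    plt.figure(figsize=(6, 6))
    plt.quiver(pvf.positions[ok, 0], pvf.positions[ok, 1],
               np.cos(np.deg2rad(pvf.direction[ok])),
               np.sin(np.deg2rad(pvf.direction[ok])), color="0.3")
    plt.scatter(*goal_xy, marker="h", s=200, c="gold", label="goal")
    plt.scatter(*ps.sink_xy, c="r", s=60, label="population sink")
    plt.legend()
    plt.axis("equal")
    plt.savefig(FIG, dpi=120, bbox_inches="tight")

    print(f"population field from {len(pairs)} significant ConSink cells")
    print(f"population sink ({ps.sink_xy[0]:.1f}, {ps.sink_xy[1]:.1f}), "
          f"MRL={ps.mrl:.3f}, {dist:.1f} cm from the goal")
    print(f"wrote {os.path.abspath(OUT)} and {os.path.abspath(FIG)}")


if __name__ == "__main__":
    main()
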