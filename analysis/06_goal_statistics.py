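#!/usr/bin/env python
"""Goal-referenced population statistics.

Using the significant ConSink cells: the fantail profile of population
firing over direction-relative-to-goal, goalward firing on correct vs
error choices during both wait periods, and the behavioural binomial test.
Writes results/goal_stats.json.
"""
import json
import os
import sys
import warnings

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from consink import goalstats, prep, synth  # noqa: E402

HERE = os.path.dirname(__file__)
SESSION = os.path.join(HERE, "..", "results", "session")
CONSINKS = os.path.join(HERE, "..", "results", "consinks.csv")
OUT = os.path.join(HERE, "..", "results", "goal_stats.json")


def main():
    warnings.filterwarnings("ignore")
    ses = synth.Session.load(SESSION)
    goal_xy = ses.maze.centers[ses.maze.goal]
    det = pd.read_csv(CONSINKS)
    sig = det[det["significant"]]
    posed, cells_ce = [], []
    for row in sig.itertuples():
        sp = prep.interpolate_pose(ses.spikes[row.cell_id], ses.tracking,
                                   row.cell_id, ses.maze)
        posed.append(sp)
        cells_ce.append({"spikes": sp, "sink": (row.sink_x, row.sink_y),
                         "preferred_rd": row.preferred_rd})

    ft = goalstats.fantail(posed, ses.tracking, goal_xy)
    peak = float(ft.bin_centers[np.nanargmax(ft.rate)])
    ce = goalstats.compare_correct_error(cells_ce, ses.task, ses.tracking,
                                         goal_xy)
    beh = goalstats.behavioural_score(ses.task)

    payload = {
        "n_consink_cells": len(posed),
        "fantail": {
            "bin_centers_deg": [float(v) for v in ft.bin_centers],
            "rate_hz_per_cell": [None if not np.isfinite(v) else float(v)
                                 for v in ft.rate],
            "peak_bin_deg": peak,
        },
        "correct_error": {
            k: {kk: vv for kk, vv in v.items()
                if isinstance(vv, (int, float, bool))}
            for k, v in ce.items()
        },
        "behaviour": beh,
    }
    with open(OUT, "w") as fh:
        json.dump(payload, fh, indent=1)

    print(f"fantail peak bin: {peak:+.0f} deg relative to goal")
    print("fantail z-profile:",
          np.array2string(ft.z, precision=2, suppress_small=True))
    for which in ("wait1", "wait2"):
        v = ce[which]
        if v["computable"]:
            print(f"{which}: goalward correct-vs-error signed-rank "
                  f"p = {v['p_goalward']:.3g} "
                  f"(median diff {v['median_goalward_diff']:+.2f} Hz)")
    print(f"behaviour: {beh['n_correct']}/{beh['n_scored']} correct, "
          f"p = {beh['binomial_p']:.2e}")
    print(f"wrote {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
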