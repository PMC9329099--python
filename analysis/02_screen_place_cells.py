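#!/usr/bin/env python
"""Screen the simulated cells for place-cell status.

Loads the session written by 01_simulate_session.py, applies the 500-spike
inclusion rule, computes spatial information and coherence with a circular
time-shift null, and writes results/screening.csv.
"""
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from consink import prep, synth  # noqa: E402

HERE = os.path.dirname(__file__)
SESSION = os.path.join(HERE, "..", "results", "session")
OUT = os.path.join(HERE, "..", "results", "screening.csv")


def main():
    ses = synth.Session.load(SESSION)
    rows = []
    for cell in ses.cells:
        sp = prep.interpolate_pose(ses.spikes[cell.cell_id], ses.tracking,
                                   cell.cell_id, ses.maze)
        row = {"cell_id": cell.cell_id, "cell_class": cell.cell_class,
               "n_spikes": sp.n, "included": sp.n >= prep.MIN_SPIKES_PER_CONDITION}
        if row["included"]:
            row.update(prep.screen_place_cell(sp, ses.tracking, n_shifts=100,
                                              seed=7))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(OUT, index=False)
    n_pc = int(df.get("is_place_cell", pd.Series(dtype=bool)).sum())
    print(df.to_string(index=False))
    print(f"\n{n_pc}/{len(df)} cells pass the place-cell screen; "
          f"wrote {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
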