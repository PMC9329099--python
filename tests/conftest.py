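import numpy as np
import pytest

from consink import prep, sinks, synth
from consink.geometry import build_honeycomb


@pytest.fixture(scope="session")
def maze():
    return build_honeycomb(goal=45)


@pytest.fixture(scope="session")
def demo_session(maze):
    """Small mixed-population session shared by the unit tests: two tuned
    ConSink cells, one place cell, one allocentric HD cell, one homogeneous
    cell, ~15 min."""
    rng = np.random.default_rng(1234)
    cells = (
        synth.make_cells(rng, maze, 2, "consink", kappa_rd=(2.0, 3.0),
                         base_rate=(2.5, 3.0))
        + synth.make_cells(rng, maze, 1, "place_only", base_rate=(2.0, 2.5))
        + synth.make_cells(rng, maze, 1, "allo_hd", kappa_ad=2.5,
                           base_rate=(2.0, 2.5), field_sigma=None)
        + synth.make_cells(rng, maze, 1, "uniform", base_rate=(2.0, 2.5),
                           field_sigma=None)
    )
    return synth.generate_session(cells, seed=4321, maze=maze, n_trials=8)


@pytest.fixture(scope="session")
def demo_posed(demo_session):
    return {
        c.cell_id: prep.interpolate_pose(
            demo_session.spikes[c.cell_id], demo_session.tracking, c.cell_id,
            demo_session.maze,
        )
        for c in demo_session.cells
    }


@pytest.fixture(scope="session")
def demo_grid(demo_session):
    return sinks.make_sink_grid(demo_session.tracking, nx=18, ny=15)


@pytest.fixture(scope="session")
def demo_ctx(demo_session, demo_grid):
    return sinks.SinkSearchContext(demo_session.tracking, demo_grid)
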