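import numpy as np
import pytest

from cox2screen import screen_scoring as sc
from cox2screen import synthetic_screen as ss
from cox2screen.reporter_kinetics import default_grid, presets, simulate_well

DEFAULT_SEED = 0
TS_SEED_OFFSET = 1000


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def dmso_traj(grid):
    return simulate_well(presets("4T1"), presets("DMSO"), grid)


@pytest.fixture(scope="session")
def default_screen():
    """The default 1280-compound screen at the default seed, fully scored."""
    lib = ss.build_library(seed=DEFAULT_SEED)
    layouts = ss.build_plate_layouts(lib)
    ts = ss.generate_timeseries(layouts, lib, seed=DEFAULT_SEED + TS_SEED_OFFSET)
    library_df = ss.library_to_frame(lib)
    platemap = ss.layouts_to_frame(layouts)
    scores = sc.score_screen(ts, platemap, library_df)
    return {
        "library": lib,
        "library_df": library_df,
        "layouts": layouts,
        "platemap": platemap,
        "timeseries": ts,
        "scores": scores,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
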