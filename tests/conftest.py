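from pathlib import Path

import numpy as np
import pytest

import wetdyn as w

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def legend():
    return w.default_legend()


@pytest.fixture(scope="session")
def table5(legend):
    """The published 15-year area-transition tabulation, classes coded 1..5."""
    from wetdyn.markov_projection import TransitionCountMatrix

    return TransitionCountMatrix.from_csv(DATA_DIR / "transition_area_matrix_1985_2000.csv")


@pytest.fixture(scope="session")
def small_grid():
    return w.GridSpec(10, 10, 30.0)


@pytest.fixture(scope="session")
def synthetic_series(legend):
    """Default-condition three-date series with drivers and truth (seed 7)."""
    cfg = w.default_config(seed=7)
    drivers = w.generate_drivers(cfg)
    maps, truth = w.generate_series(cfg, drivers)
    return cfg, drivers, maps, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_categorical(rng, n_rows=20, n_cols=20, codes=(1, 2, 3, 4, 5), cell_size=30.0):
    grid = w.GridSpec(n_rows, n_cols, cell_size)
    values = rng.choice(codes, size=grid.shape)
    return w.CategoricalRaster(grid, values)
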