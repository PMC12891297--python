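"""Shared fixtures: a small synthetic landscape and fast model fits."""

import warnings

import numpy as np
import pytest

from chacoedge import (
    EdgeEffectsRegressor,
    LandscapeConfig,
    generate_landscape,
    sample_points,
    simulate_structure,
    standardize,
)

warnings.filterwarnings("ignore", category=FutureWarning)

#: Small, fast landscape used by most unit tests (6 x 6 km at 50-m cells).
SMALL_CFG = dict(
    n_rows=120,
    n_cols=120,
    cell_size=50.0,
    n_plots=10,
    plot_side_range=(250.0, 700.0),
    placement_margin=1200.0,
    n_homesteads=8,
    n_roads=3,
)


@pytest.fixture(scope="session")
def small_landscape():
    land, plots = generate_landscape(LandscapeConfig(**SMALL_CFG), seed=42)
    simulate_structure(land, plots, seed=43)
    return land, plots


@pytest.fixture(scope="session")
def small_points(small_landscape):
    land, plots = small_landscape
    return sample_points(
        land, plots, n=400, max_distance=800.0, boundary_buffer=1000.0, seed=44
    )


@pytest.fixture(scope="session")
def agb_design(small_points):
    return standardize(small_points, "agb")


@pytest.fixture(scope="session")
def fast_fit(agb_design):
    est = EdgeEffectsRegressor(include_age=False, iterations=600, warmup=200, seed=7)
    return est.fit(agb_design)


@pytest.fixture(scope="session")
def fast_fit_age(agb_design):
    est = EdgeEffectsRegressor(include_age=True, iterations=600, warmup=200, seed=8)
    return est.fit(agb_design)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
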