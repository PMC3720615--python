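import numpy as np
import pytest

from latgrad import (ScenarioConfig, build_grid, generate_scenario, rasterize)


@pytest.fixture(scope="session")
def small_scenario():
    """Compact scenario: 40 species over a narrow continental strip."""
    return ScenarioConfig(
        n_species=40, bbox=(-30.0, 0.0, -25.0, 25.0),
        rd_latitude_coupling=-0.8, richness_gradient=2.0,
        polytomy_prob=0.1, seed=11,
    )


@pytest.fixture(scope="session")
def small_run(small_scenario):
    """Tree, ranges and truth table for the compact scenario."""
    return generate_scenario(small_scenario)


@pytest.fixture(scope="session")
def small_presence(small_scenario, small_run):
    """Presence matrix of the compact scenario on a 100 km grid."""
    _, ranges, _ = small_run
    grid = build_grid(small_scenario.bbox)
    return rasterize(ranges, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
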