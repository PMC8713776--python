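import pytest

from roadhia.pipeline import Analysis, RunConfig
from roadhia.synthetic_world import WorldConfig, generate_world

#: A compact two-year world: big enough to have urban/rural contrast and
#: multiple states, small enough for brute-force oracles.
SMALL_CONFIG = WorldConfig(
    grid_nx=8, grid_ny=8, cell_km=5.0,
    n_counties=4, n_states=2, n_msas=1,
    seed=7, years=(2008, 2017), urban_fraction=0.5,
)


@pytest.fixture(scope="session")
def small_world():
    return generate_world(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_analysis():
    return Analysis(RunConfig(world=SMALL_CONFIG))


@pytest.fixture(scope="session")
def demo_analysis():
    """The default demo configuration (20×20 grid, 16 counties, 4 years)."""
    return Analysis(RunConfig())
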