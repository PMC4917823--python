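import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import saltmarsh as sm

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def species():
    return sm.default_species_params()


@pytest.fixture(scope="session")
def default_landscape():
    """The standard synthetic shore (200x200, 1 m cells, seed 42)."""
    return sm.make_initial_state()


@pytest.fixture()
def small_landscape():
    """A 60x40 shore, cheap enough for per-test runs."""
    spec = sm.LandscapeSpec(n_rows=60, n_cols=40, seed=7)
    return sm.make_initial_state(spec)


@pytest.fixture()
def flat_state():
    """A uniform 9x9 mudflat at 2.2 m with one empty seed bank per species."""
    spec = sm.GridSpec(9, 9, cell_size=1.0)
    elev = sm.ElevationGrid(spec, np.full((9, 9), 2.2))
    hab = sm.HabitatGrid(spec, np.full((9, 9), int(sm.Habitat.MUDFLAT), dtype=np.int16))
    state = sm.LandscapeState(year=2008, elev=elev, hab=hab, seedbank={})
    state.ensure_seedbanks(sm.default_species_params())
    return state
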