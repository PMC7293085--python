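import numpy as np
import pytest

from cyanocline import simulate


@pytest.fixture(scope="session")
def small_bundle():
    """A small deterministic 6-city study reused across modules."""
    scenarios = simulate.default_scenarios(
        n_cities=6, n_populations=20, plants_per_population=15, years=3
    )
    return simulate.generate_multi_city_study(
        scenarios, slope_climate_coupling=-1.5, seed=1234
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
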