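import dataclasses

import pytest

from rootflux.simulate import default_generator_spec, generate_study


@pytest.fixture(scope="session")
def default_spec():
    return default_generator_spec(seed=0)


@pytest.fixture(scope="session")
def default_obs(default_spec):
    """One calibrated synthetic study (3 x 16 x 3 x 5 = 720 observations)."""
    return generate_study(default_spec)


@pytest.fixture(scope="session")
def small_obs():
    """A reduced study (4 tubes) for fast model fits."""
    spec = dataclasses.replace(default_generator_spec(seed=7, n_tubes=4), tube_sd=0.0)
    return generate_study(spec)
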