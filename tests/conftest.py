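import numpy as np
import pytest
from hypothesis import settings

from pmroutes.synthetic import gen_study, six_route_preset

settings.register_profile("ci", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def six_routes():
    """The bundled six-route synthetic study at a fixed seed."""
    return gen_study(six_route_preset(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
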