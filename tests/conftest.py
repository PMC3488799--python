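import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mouse_model():
    from ctclab.models.mouse import make_neonatal_mouse_model

    return make_neonatal_mouse_model()


@pytest.fixture(scope="session")
def human_model():
    from ctclab.models.human import make_human_recipient_model

    return make_human_recipient_model()


@pytest.fixture(scope="session")
def suite():
    from ctclab.templates import build_suite

    return build_suite()


@pytest.fixture(scope="session")
def start_params():
    from ctclab.templates import starting_point_params

    return starting_point_params()


@pytest.fixture(scope="session")
def mouse_baseline_trace(mouse_model):
    from ctclab.models import SimSettings

    model, _ = mouse_model
    return model.simulate_paced(settings=SimSettings(dt=0.1, beats=4))


@pytest.fixture(scope="session")
def human_trace(human_model):
    from ctclab.models import SimSettings

    model, _ = human_model
    return model.simulate_paced(settings=SimSettings(dt=0.01, beats=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
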