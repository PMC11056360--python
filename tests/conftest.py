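import pytest
from hypothesis import HealthCheck, settings

import brimplan as bp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ml_mean_model():
    """Noise-free model built from the ML group's mean zone lengths."""
    model, truth = bp.build_pelvis(bp.reference_mean_spec("ML"), seed=0)
    return model, truth


@pytest.fixture(scope="session")
def ml_zones(ml_mean_model):
    model, _ = ml_mean_model
    lm = bp.compute_landmarks(model)
    return bp.zone_lengths(model, lm), lm


@pytest.fixture(scope="session")
def span_table():
    return bp.builtin_span_table()


@pytest.fixture(scope="session")
def mean_plate():
    from brimplan.plates import mean_plate

    return mean_plate()
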