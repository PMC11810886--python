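import pytest
from hypothesis import HealthCheck, settings

from stcr import GroundTruth, TrialDesign, generate_trial

settings.register_profile(
    "stcr",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("stcr")


@pytest.fixture(scope="session")
def default_design():
    return TrialDesign()


@pytest.fixture(scope="session")
def zero_noise_truth():
    return GroundTruth(uptake_noise_cv=0.0, yield_noise_cv=0.0)


@pytest.fixture(scope="session")
def default_truth():
    return GroundTruth()


@pytest.fixture(scope="session")
def zero_noise_plots(default_design, zero_noise_truth):
    return generate_trial(default_design, zero_noise_truth, seed=7)


@pytest.fixture(scope="session")
def noisy_plots(default_design, default_truth):
    return generate_trial(default_design, default_truth, seed=7)
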