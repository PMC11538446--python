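import numpy as np
import pytest
from hypothesis import settings

import capnosvo as c

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants():
    return c.PhysioConstants()


@pytest.fixture(scope="session")
def steady_truth():
    """Constant-baseline hemodynamic trajectory (no events)."""
    return c.run_scenario([], c.ScenarioParams(), duration_s=3000.0)


@pytest.fixture(scope="session")
def steady_breaths(steady_truth):
    return c.synthesize_breaths(steady_truth, c.ScenarioParams())


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Full 10-animal protocol with all measurement noise, lag and drift off."""
    return c.simulate_cohort(
        model=c.MeasurementModel.noiseless(), n_animals=10, seed=7
    )


@pytest.fixture(scope="session")
def noisy_cohort():
    """Full 10-animal protocol under the default measurement model."""
    return c.simulate_cohort(n_animals=10, seed=7)
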