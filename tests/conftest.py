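"""Shared fixtures.

Closed-loop runs use dt = 2e-4 s (half the production default): the
step-halving check in the simulator suite bounds the discretization error
of the cycle means at well under 0.5%, and the coarser grid keeps the
whole suite fast.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_tables():
    from shuntloop.config import default_tables

    return default_tables()


@pytest.fixture(scope="session")
def baseline_result():
    """Converged periodic run of the baseline (occluded-shunt) closed loop."""
    from shuntloop.config import RunConfig, run_model

    return run_model(RunConfig(model="figure1_baseline", dt=2e-4, max_cycles=60))


@pytest.fixture(scope="session")
def flared_result():
    from shuntloop.config import RunConfig, run_model

    return run_model(RunConfig(model="figure1_flared", dt=2e-4, max_cycles=60))


@pytest.fixture(scope="session")
def virtual_patient():
    """Noise-free virtual patient from the single-ventricle ejection loop."""
    from shuntloop.synthetic import gen_patient_waveforms

    return gen_patient_waveforms(noise_sigma=0.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
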