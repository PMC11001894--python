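import numpy as np
import pytest
from hypothesis import settings

from rloopkit.pipeline import run_synthetic_study
from rloopkit.simulate import SimulationDesign

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_design() -> SimulationDesign:
    return SimulationDesign(seed=1)


@pytest.fixture(scope="session")
def study(default_design):
    """One full synthetic study run shared by the end-to-end tests."""
    return run_synthetic_study(default_design)


@pytest.fixture(scope="session")
def null_study():
    """Study with no condition difference (loss_fraction = 0)."""
    return run_synthetic_study(
        SimulationDesign(seed=2, loss_fraction=0.0), with_irr_expression=False
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
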