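import pytest

from adjuvance.synthetic_params import generate_parameter_set
from adjuvance.workbench import ModelRunner


@pytest.fixture(scope="session")
def params():
    """One synthetic parameter set shared across the suite."""
    return generate_parameter_set(seed=1)


@pytest.fixture(scope="session")
def capox_runner(params):
    return ModelRunner(params, "CAPOX")


@pytest.fixture(scope="session")
def folfox_runner(params):
    return ModelRunner(params, "FOLFOX")


@pytest.fixture(scope="session")
def base_outcomes(capox_runner, folfox_runner):
    """Base-case endpoints for all four strategy arms."""
    return {
        ("CAPOX", 6): capox_runner.outcomes(6),
        ("CAPOX", 3): capox_runner.outcomes(3),
        ("FOLFOX", 6): folfox_runner.outcomes(6),
        ("FOLFOX", 3): folfox_runner.outcomes(3),
    }
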