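import pytest

from bystander.design import generate_experiment
from bystander.features import add_features


@pytest.fixture(scope="session")
def exp1_schedule():
    """Six-participant experiment-1 schedule with features."""
    return add_features(generate_experiment(1, 6, 123))


@pytest.fixture(scope="session")
def exp2_schedule():
    """Six-participant experiment-2 schedule with features."""
    return add_features(generate_experiment(2, 6, 123))
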