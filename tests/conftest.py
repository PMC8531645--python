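import pytest
from hypothesis import settings

from contusim.sensitivity import analyze
from contusim.standin import StandInModel
from contusim.surrogate import TrainingConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standin_model() -> StandInModel:
    """Reference stand-in simulator (null mode on)."""
    return StandInModel()


@pytest.fixture(scope="session")
def small_training_config() -> TrainingConfig:
    """Reduced ensemble config for fast unit tests (not the accuracy bar)."""
    return TrainingConfig(n_members=2, max_epochs=600, patience=600, base_seed=7)


@pytest.fixture(scope="session")
def standin_sensitivity(standin_model):
    """Full-size sensitivity analysis of the stand-in: 10,000 LHS samples,
    both indicators for all 7 inputs x 4 outputs. Shared across tests."""
    return analyze(standin_model, n=10_000, seed=1234)
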