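import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from guiltgame import ModelParams

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def default_params() -> ModelParams:
    """The headline parameter set: long encounters, rare errors, convincing
    fakers, moderate symmetric apology costs."""
    return ModelParams(n=0.95, a=0.01, p=0.95, c=0.4, d=0.4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
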