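import numpy as np
import pytest

from dyadsync.events import TrialCondition
from dyadsync.simulate import AgentParams, EffectConfig, simulate_dyad_trial


@pytest.fixture
def condition():
    return TrialCondition("dyad01", 1, 550.0, 200.0, 5)


@pytest.fixture
def noisy_trial(condition):
    """One reproducible noisy dyadic trial at default parameters."""
    return simulate_dyad_trial(
        condition, AgentParams(), AgentParams(), EffectConfig(), rng_seed=42
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
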