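import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


class StubObserver:
    """Deterministic observer stub: step psychometric profile for tracing
    the staircase, or any fixed p(level) function."""

    def __init__(self, p_fn, animal_id=0):
        self._p = p_fn
        self.animal_id = animal_id

    def prob_correct(self, level, domain, eye="both", task="V_vs_H"):
        return self._p(level)


@pytest.fixture
def stub_observer():
    return StubObserver
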