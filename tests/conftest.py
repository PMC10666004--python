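import numpy as np
import pytest

from rdnasim import ScenarioParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """A minimal valid scenario for unit tests (fast to simulate)."""
    def factory(**overrides):
        base = dict(
            initial_cn=100,
            n_divisions=3,
            n_flies=2,
            n_gsc_per_fly=2,
            usce_freq_gsc=0.0,
            usce_freq_sg=0.0,
            gsc_gain_bias=0.5,
            seed=7,
            label="tiny",
        )
        base.update(overrides)
        return ScenarioParams(**base)
    return factory
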