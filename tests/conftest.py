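import numpy as np
import pytest

from rstdp.core import PlasticityRule, SimGrid


@pytest.fixture
def grid():
    return SimGrid(dt=0.001, epsilon=0.001)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(params=["additive", "symmetric", "corticostriatal"])
def rule_kind(request):
    return request.param


@pytest.fixture
def make_rule():
    def _make(kind, alpha=1.0, lambda_rate=0.01, **kw):
        return PlasticityRule(kind, alpha=alpha, lambda_rate=lambda_rate, **kw)
    return _make
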