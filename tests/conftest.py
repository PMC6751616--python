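import numpy as np
import pytest

from seqsafe.elicitation import FitConfig
from seqsafe.mixtures import BetaMixture

EVENTS = ("death", "ivh", "nec", "ret")
CONTROL_RATES = (0.39, 0.15, 0.06, 0.04)
WEIGHTS = (100, 88, 70, 60)
TAU_FINALS = (0.63, 0.60, 0.82, 0.71)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def fast_fit_config():
    """Reduced restarts / capped cuts to keep fitting tests quick."""
    return FitConfig(n_restarts=3, max_cut_candidates=40)


@pytest.fixture
def two_component_mixture():
    return BetaMixture(shapes=((2.0, 40.0), (10.0, 30.0)), weights=(0.6, 0.4))


@pytest.fixture
def narrow_margin():
    """Margin concentrated near 0.05 (mean of Beta(2, 38))."""
    return BetaMixture(shapes=((2.0, 38.0),), weights=(1.0,))
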