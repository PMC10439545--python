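import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20230818)


@pytest.fixture
def infeasible_spec():
    """Skewed means plus strong positive correlation: the order-2 truncation
    assigns negative mass to the discordant outcome (1, 0)."""
    from bahadur import Order2Spec

    return Order2Spec.from_correlation([0.05, 0.95], [[1.0, 0.9], [0.9, 1.0]])
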