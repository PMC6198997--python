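import numpy as np
import pytest

from hbboundary.models import PromoterModel, RateSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_state():
    """Symmetric one-site promoter: P(active) = 0.5 at the boundary."""
    return PromoterModel(
        RateSet("eq_chain", [1.0], [1.0], N=1), boundary_calibrated=True
    )


@pytest.fixture
def chain_n2():
    """Two-site chain with effective constants (1, 1, 2): calibrated."""
    return PromoterModel(
        RateSet("eq_chain", [1.0, 2.0], [1.0, 1.0], N=2), boundary_calibrated=True
    )


def random_neq_model(rng, lo=0.05, hi=5.0):
    b = rng.uniform(lo, hi, 12)
    u = rng.uniform(lo, hi, 12)
    return PromoterModel(RateSet("neq_graph", b, u, N=3))


def random_hybrid_model(rng, lo=0.05, hi=5.0):
    b = rng.uniform(lo, hi, 15)
    u = rng.uniform(lo, hi, 15)
    return PromoterModel(RateSet("hybrid", b, u, N=6))
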