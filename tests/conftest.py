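import numpy as np
import pytest

from hypercast.core import aggregate
from hypercast.synthetic import SynthSpec, generate_markov_hypergraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def markov_net():
    """Memory-rich synthetic hypergraph (promotion-consistent snapshots)."""
    spec = SynthSpec(horizon=120, seed=1, enforce_maximality=True)
    return generate_markov_hypergraph(spec)


@pytest.fixture(scope="session")
def markov_agg(markov_net):
    return aggregate(markov_net)
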