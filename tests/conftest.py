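import numpy as np
import pytest

from hrnn.evolution import GAConfig, init_population
from hrnn.model import CandidateNetwork, NeuronSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fig_network():
    """A 3-neuron candidate with 2 context nodes over 5 genes (C=3, so
    context nodes are x1..x3 and genes x4..x8), target gene x8: neuron 1
    reads chain context x1 and gene x4; neuron 2 reads x1 (chain), x2 and
    gene x5; neuron 3 reads gene x7 only."""
    return CandidateNetwork(
        P=5, C=3, c=2, target_gene=5,
        neurons=[
            NeuronSpec([1, 4], [1.2, -0.7]),
            NeuronSpec([2, 1, 5], [0.9, 0.4, 1.5]),
            NeuronSpec([7], [2.0]),
        ],
        mu=None,
    )


def random_candidates(n, P=5, C=3, target_gene=1, seed=0):
    """Pool of random valid candidates for property scans."""
    cfg = GAConfig(population_size=n, elite_count=min(2, n - 1))
    return init_population(P, C, target_gene, cfg, rng=np.random.default_rng(seed))
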