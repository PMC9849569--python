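import numpy as np
import pytest

import symptomnet as sn


@pytest.fixture(scope="session")
def default_cohort():
    """One study-shaped synthetic cohort shared across tests."""
    spec = sn.CohortSpec(seed=1)
    panel = sn.generate_cohort(spec)
    return panel, spec


@pytest.fixture(scope="session")
def strong_model():
    """Small dense model with strong edges for near-deterministic estimation."""
    rng = np.random.default_rng(42)
    return sn.generate_true_network(p=6, density=0.5, seed=rng)


def random_network(rng, p, density=0.4):
    """Random SymptomNetwork with a two-community partition, for oracles."""
    nodes = tuple(f"N{i}" for i in range(p))
    W = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    mask = rng.random(len(iu[0])) < density
    vals = rng.uniform(0.1, 0.9, len(iu[0])) * rng.choice([-1, 1], len(iu[0]))
    W[iu[0][mask], iu[1][mask]] = vals[mask]
    W = W + W.T
    half = p // 2
    partition = sn.CommunityPartition(
        {n: ("depression" if i < half else "anxiety")
         for i, n in enumerate(nodes)}
    )
    return sn.SymptomNetwork(nodes, W, partition, n=100, lambda_selected=0.1)
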