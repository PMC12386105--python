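import numpy as np
import pytest

from mircoop.config import RunConfig
from mircoop.io import ExpressionDataset, KnowledgeTable
from mircoop.synthetic import SimulationSpec, simulate


@pytest.fixture
def tiny_data() -> ExpressionDataset:
    """Six samples, three features; feature f1 separates the groups."""
    rng = np.random.default_rng(7)
    values = rng.normal(size=(6, 3))
    values[:3, 0] += 4.0  # cases shifted on f1
    return ExpressionDataset(
        feature_ids=["f1", "f2", "f3"],
        sample_ids=[f"s{i}" for i in range(6)],
        values=values,
        labels=np.array([1, 1, 1, 0, 0, 0]),
    )


@pytest.fixture
def tiny_knowledge(tiny_data) -> KnowledgeTable:
    return KnowledgeTable(
        feature_ids=list(tiny_data.feature_ids),
        disease_ids=["d1", "d2"],
        assoc=np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
    )


@pytest.fixture(scope="session")
def benchmark():
    """The standard planted-module benchmark instance (seed 0)."""
    return simulate(SimulationSpec(seed=0))


@pytest.fixture
def fast_config() -> RunConfig:
    """Defaults shrunk for unit-test speed (fewer epochs, small dims)."""
    return RunConfig(epochs=20, hidden_dims=(8, 4), discriminator_dim=3, seed=0)


def split_holdout(spec_seed: int):
    """One generator draw with 60 per group, split 30+30 train / 30+30 test.

    Train and test share the planted-module placement and knowledge, so the
    test half is a genuine held-out sample from the same population.
    """
    data, know, truth = simulate(SimulationSpec(n_per_group=60, seed=spec_seed))
    y = data.labels
    case = np.flatnonzero(y == 1)
    ctrl = np.flatnonzero(y == 0)
    train = data.subset_samples(np.concatenate([case[:30], ctrl[:30]]))
    test = data.subset_samples(np.concatenate([case[30:], ctrl[30:]]))
    return train, test, know, truth
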