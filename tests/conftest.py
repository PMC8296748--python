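import numpy as np
import pytest

from braingat import (GAT2, SyntheticSpec, TrainConfig,
                      generate_synthetic_dataset)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic dataset shared across tests (30-node graphs)."""
    spec = SyntheticSpec(n_graphs=60, n_nodes=12, n_selected=6, seed=7)
    return generate_synthetic_dataset(spec)


@pytest.fixture(scope="session")
def micro_graphs():
    """A handful of 5-node graphs for oracle comparisons."""
    spec = SyntheticSpec(n_graphs=8, n_nodes=5, n_selected=2, seed=11)
    return generate_synthetic_dataset(spec).graphs


@pytest.fixture(scope="session")
def untrained_gat2(micro_graphs):
    return GAT2(micro_graphs, heads=(2, 2), units=(3, 3), seed=5)


@pytest.fixture(scope="session")
def trained_tiny_gat2(tiny_dataset):
    """A briefly trained model on the tiny dataset (shared, read-only)."""
    graphs = tiny_dataset.graphs
    model = GAT2(graphs[:48], heads=(2, 2), units=(8, 8), seed=3)
    model.fit(TrainConfig(max_epochs=15, patience=15, seed=3,
                          learning_rate=1e-3),
              val_graphs=graphs[48:])
    return model
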