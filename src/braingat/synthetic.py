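"""Synthetic labeled weighted-graph benchmark.

Generates complete graphs whose binary label is a thresholded linear
functional of the edge weights: a fixed subset of ``n_selected`` nodes is
drawn once per dataset; for each graph W1 is the total weight inside the
subset, W2 the total weight crossing it, and W0 = 2*W1 + W2.  Graphs with
W0 above the dataset-wide mean of W0 form the positive class.  Node
features mirror the brain-network construction: each node's feature
vector is its row of the weight matrix with a unit diagonal.

The defaults (4000 graphs, 30 nodes, 15 selected, uniform(0,1) weights)
are the benchmark's standard conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import GraphSample

__all__ = ["SyntheticSpec", "SyntheticDataset",
           "generate_synthetic_dataset", "split_folds"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_graphs: int = 4000
    n_nodes: int = 30
    n_selected: int = 15
    seed: int = 0
    weight_low: float = 0.0
    weight_high: float = 1.0

    def __post_init__(self):
        if not (0 < self.n_selected < self.n_nodes):
            raise ValueError("need 0 < n_selected < n_nodes")
        if self.n_graphs < 2:
            raise ValueError("need at least 2 graphs")
        if not self.weight_low < self.weight_high:
            raise ValueError("need weight_low < weight_high")


@dataclass
class SyntheticDataset:
    graphs: list[GraphSample]
    selected_nodes: np.ndarray
    w0_values: np.ndarray
    w0_mean: float
    spec: SyntheticSpec | None = None

    @property
    def labels(self) -> np.ndarray:
        return np.array([g.label for g in self.graphs], dtype=int)

    def __len__(self) -> int:
        return len(self.graphs)


def _functionals(weights: np.ndarray, in_sel: np.ndarray) -> tuple[float, float]:
    """W1 (within-subset) and W2 (subset-complement) weight sums.

    Each undirected edge is counted once; the diagonal is excluded.
    """
    iu, ju = np.triu_indices(weights.shape[0], k=1)
    w = weights[iu, ju]
    both = in_sel[iu] & in_sel[ju]
    cross = in_sel[iu] ^ in_sel[ju]
    return float(w[both].sum()), float(w[cross].sum())


def generate_synthetic_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the complete-graph benchmark described above.

    Labeling is two-pass: all W0 values are computed first, then compared
    with their empirical mean (strictly greater -> Class-one = 1).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    selected = np.sort(rng.choice(n, size=spec.n_selected, replace=False))
    in_sel = np.zeros(n, dtype=bool)
    in_sel[selected] = True

    iu, ju = np.triu_indices(n, k=1)
    weight_mats = []
    w0 = np.empty(spec.n_graphs)
    for g in range(spec.n_graphs):
        vals = rng.uniform(spec.weight_low, spec.weight_high, size=iu.size)
        w = np.zeros((n, n))
        w[iu, ju] = vals
        w += w.T
        w1, w2 = _functionals(w, in_sel)
        w0[g] = 2.0 * w1 + w2
        weight_mats.append(w)
    w0_mean = float(w0.mean())

    graphs = []
    for g, w in enumerate(weight_mats):
        feats = w.copy()
        np.fill_diagonal(feats, 1.0)
        label = int(w0[g] > w0_mean)
        adj = w.copy()
        np.fill_diagonal(adj, 1.0)  # self-loops, as in the brain networks
        graphs.append(GraphSample(node_features=feats, adj_weights=adj,
                                  label=label, sample_id=f"synth-{g:05d}"))
    return SyntheticDataset(graphs=graphs, selected_nodes=selected,
                            w0_values=w0, w0_mean=w0_mean, spec=spec)


def split_folds(n_samples_or_dataset, k: int, seed: int = 0
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic shuffled k-fold partition.

    Returns ``k`` (train_idx, test_idx) pairs; test folds are disjoint,
    exhaustive, and their sizes differ by at most 1.
    """
    n = (len(n_samples_or_dataset)
         if not isinstance(n_samples_or_dataset, (int, np.integer))
         else int(n_samples_or_dataset))
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_folds = np.array_split(order, k)
    out = []
    for i in range(k):
        test = np.sort(test_folds[i])
        train = np.sort(np.concatenate(
            [test_folds[j] for j in range(k) if j != i]))
        out.append((train, test))
    return out
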