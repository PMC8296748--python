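"""Construction of weighted functional brain networks.

A subject's resting-state recording is summarized as an N x N Pearson
correlation matrix between the mean time series of N regions of interest
(ROIs).  Each ROI becomes a graph node whose feature vector is its full
connectivity profile (the corresponding *signed* row of the correlation
matrix), while edge weights are the *absolute* correlations, optionally
sparsified by a strict threshold.  Self-correlations (the unit diagonal)
count as edges, so a dense N-node network has N^2 adjacency entries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesTable",
    "ConnectivityMatrix",
    "GraphSample",
    "pearson_connectivity",
    "build_graph",
    "flatten_upper_triangle",
    "sparsity_of",
]


@dataclass
class TimeSeriesTable:
    """Mean ROI time series: T timepoints by N regions."""

    values: np.ndarray
    region_ids: list[str]
    sample_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a T x N matrix")
        t, n = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if n < 2:
            raise ValueError(f"need at least 2 regions, got {n}")
        if len(self.region_ids) != n:
            raise ValueError("region_ids length does not match columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains missing/non-finite values")

    @classmethod
    def from_file(cls, path, sample_id: str = "") -> "TimeSeriesTable":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep)
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns],
                   sample_id=sample_id or str(path))


@dataclass
class ConnectivityMatrix:
    """Symmetric matrix of pairwise Pearson correlations, unit diagonal."""

    rho: np.ndarray
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        n = self.rho.shape[0]
        if self.rho.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not self.region_ids:
            self.region_ids = [str(i) for i in range(n)]
        if not np.allclose(self.rho, self.rho.T, atol=1e-8):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-8):
            raise ValueError("connectivity diagonal must be 1")
        if np.any(np.abs(self.rho) > 1 + 1e-8):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.rho.shape[0]


@dataclass
class GraphSample:
    """One classified weighted graph.

    ``node_features`` keeps the signed correlation rows; ``adj_weights``
    holds absolute correlations after thresholding.  ``label`` is 1 for
    the positive class (ASD-like / Class-one) and 0 otherwise.
    """

    node_features: np.ndarray
    adj_weights: np.ndarray
    label: int
    sample_id: str = ""
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.adj_weights = np.asarray(self.adj_weights, dtype=float)
        n = self.node_features.shape[0]
        if self.adj_weights.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if np.any(self.adj_weights < 0) or np.any(self.adj_weights > 1 + 1e-8):
            raise ValueError("adjacency weights must lie in [0, 1]")
        if not np.allclose(self.adj_weights, self.adj_weights.T, atol=1e-8):
            raise ValueError("adjacency must be symmetric")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not self.region_ids:
            self.region_ids = [str(i) for i in range(n)]

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_features(self) -> int:
        return self.node_features.shape[1]

    def neighbor_sets(self) -> list[np.ndarray]:
        """Index set N_i per node: nodes with nonzero adjacency (self
        included whenever the diagonal survives thresholding)."""
        return [np.nonzero(self.adj_weights[i] > 0)[0]
                for i in range(self.n_nodes)]

    def neighbor_mask(self) -> np.ndarray:
        return self.adj_weights > 0


def pearson_connectivity(ts: TimeSeriesTable) -> ConnectivityMatrix:
    """Pairwise Pearson correlation between ROI time series.

    Constant (zero-variance) columns have undefined correlation; their
    off-diagonal entries are set to 0 with a warning so that batch
    construction survives one flat ROI.
    """
    x = ts.values
    sd = x.std(axis=0)
    constant = sd == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = np.corrcoef(x, rowvar=False)
    rho = np.nan_to_num(rho, nan=0.0)
    if constant.any():
        bad = [ts.region_ids[i] for i in np.nonzero(constant)[0]]
        logger.warning("constant time series for regions %s: correlations "
                       "set to 0", bad)
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    return ConnectivityMatrix(rho, list(ts.region_ids))


def build_graph(cm: ConnectivityMatrix, label: int,
                threshold: float | None = None,
                sample_id: str = "") -> GraphSample:
    """Turn a connectivity matrix into a classified graph.

    Edge weights are |rho|; with a threshold t only entries with
    |rho| > t (strictly) are retained.  Node features keep the signed
    rows regardless of thresholding.
    """
    if threshold is not None and not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    adj = np.abs(cm.rho)
    if threshold is not None:
        adj = np.where(adj > threshold, adj, 0.0)
    return GraphSample(node_features=cm.rho.copy(), adj_weights=adj,
                       label=int(label), sample_id=sample_id,
                       region_ids=list(cm.region_ids))


def flatten_upper_triangle(cm: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Strictly-upper-triangular entries in row-major order.

    Length N(N-1)/2; e.g. N=110 gives 5995 — the feature vector fed to
    the non-graph classifiers.
    """
    m = cm.rho if isinstance(cm, ConnectivityMatrix) else np.asarray(cm)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def sparsity_of(g: GraphSample) -> float:
    """Fraction of adjacency entries zeroed out relative to the dense
    count N^2 (the dense network has sparsity 0)."""
    n = g.n_nodes
    nonzero = int(np.count_nonzero(g.adj_weights))
    return 1.0 - nonzero / (n * n)
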