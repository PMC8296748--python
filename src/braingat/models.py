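"""Graph neural network models for whole-graph classification.

The flagship model, GAT2, stacks masked multi-head graph attention
layers (node representation learning) and a learned attention readout
(pooling-and-prediction):

* attention coefficients  a_ij = softmax_j(LeakyReLU(a^T [W h_i || W h_j]))
  normalized over the structural neighborhood N_i only;
* hidden layers concatenate K head outputs, the last layer averages them;
* pooling maps each node's representation to a scalar P_i = sigmoid(W^p h'_i),
  giving a graph vector P of length N;
* prediction weighs nodes by A = softmax(W^A P) and outputs the convex
  combination prob = sum_i A_i P_i in (0, 1).

Comparison heads swap the readout: GAT-average predicts mean(P); GAT-fc
flattens node representations into a dense softmax classifier; GAT-learn
pools with a learned cluster-assignment vector (Y_pool = S^T Y).  The
GCN-at variants replace the attention layers with spectral graph
convolutions (first-order or Chebyshev) feeding the same
pooling-and-prediction part.

Models follow the Model/Results convention: construct from data, call
``fit`` to obtain a Results object carrying fitted parameters, the
training history and evaluation helpers.
"""

from __future__ import annotations

import numpy as np

from .graphs import GraphSample
from .tensor import Tensor, constant, parameter

__all__ = [
    "GATLayer", "GCNLayer", "DenseLayer",
    "attention_pool", "attention_predict", "gat_average_predict",
    "learn_pool",
    "GAT2", "GATAverage", "GATFC", "GATLearn", "GCNAttention",
    "graphs_to_arrays", "binary_cross_entropy",
    "ABIDE_ARCH", "SYNTHETIC_ARCH",
]

#: reference architecture for the 110-node brain networks
ABIDE_ARCH = {"heads": (5, 3), "units": (24, 3)}
#: reference architecture for the 30-node synthetic benchmark
SYNTHETIC_ARCH = {"heads": (4, 4), "units": (16, 16)}

_EPS = 1e-12


def graphs_to_arrays(graphs: list[GraphSample]
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a list of graphs into (features, adjacency weights, labels).

    The adjacency carries the |rho| edge weights; its nonzero pattern is
    the neighbor mask used by the attention layers.
    """
    x = np.stack([g.node_features for g in graphs])
    adj = np.stack([g.adj_weights for g in graphs])
    y = np.array([g.label for g in graphs], dtype=float)
    return x, adj, y


def binary_cross_entropy(prob: Tensor, y: np.ndarray) -> Tensor:
    p = prob * (1.0 - 2.0 * _EPS) + _EPS
    yv = constant(y)
    return -(yv * p.log() + (1.0 - yv) * (1.0 - p).log()).mean()


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class GATLayer:
    """Masked multi-head graph attention layer.

    ``combine='concat'`` applies the activation per head and concatenates
    (hidden layers); ``combine='average'`` averages head outputs before
    the activation (final layer).
    """

    def __init__(self, in_dim: int, out_dim: int, heads: int,
                 combine: str = "concat", activation: str = "leaky_relu",
                 slope: float = 0.2, bias: bool = True,
                 edge_weight_mode: str = "none",
                 attn_init_scale: float = 0.05,
                 rng: np.random.Generator | None = None):
        if heads < 1 or out_dim < 1:
            raise ValueError("heads and out_dim must be >= 1")
        if combine not in ("concat", "average"):
            raise ValueError(f"unknown combine mode {combine!r}")
        if edge_weight_mode not in ("none", "multiply"):
            raise ValueError(f"unknown edge_weight_mode {edge_weight_mode!r}")
        rng = rng or np.random.default_rng(0)
        self.in_dim, self.out_dim, self.heads = in_dim, out_dim, heads
        self.combine, self.activation, self.slope = combine, activation, slope
        self.edge_weight_mode = edge_weight_mode
        self.W = parameter((heads, in_dim, out_dim), rng)
        # The attention vector a in R^{2F'} split into its source/target
        # halves.  Initialized small so the attention softmax starts close
        # to uniform: early training then behaves like stable mean
        # aggregation, and the layers sharpen attention only where the
        # data supports it.
        bound = attn_init_scale * np.sqrt(1.0 / out_dim)
        self.a_src = parameter(rng.uniform(-bound, bound, (heads, out_dim, 1)))
        self.a_dst = parameter(rng.uniform(-bound, bound, (heads, out_dim, 1)))
        self.b = parameter(np.zeros(out_dim)) if bias else None

    @property
    def width(self) -> int:
        return self.out_dim * (self.heads if self.combine == "concat" else 1)

    def parameters(self) -> list[Tensor]:
        ps = [self.W, self.a_src, self.a_dst]
        if self.b is not None:
            ps.append(self.b)
        return ps

    def _act(self, t: Tensor) -> Tensor:
        if self.activation == "leaky_relu":
            return t.leaky_relu(self.slope)
        if self.activation == "sigmoid":
            return t.sigmoid()
        if self.activation == "identity":
            return t
        raise ValueError(f"unknown activation {self.activation!r}")

    def attention(self, x: Tensor, adj: np.ndarray
                  ) -> tuple[Tensor, Tensor]:
        """Per-head attention coefficients (B, K, N, N) and projected
        features W h (B, K, N, F').

        ``adj`` may be a boolean neighbor mask or the non-negative weight
        matrix; nonzero entries define the neighborhoods.  In the
        ``multiply`` edge-weight mode the masked-softmax coefficients are
        rescaled by the edge weights and renormalized.
        """
        b, n, f = x.shape
        mask = adj > 0 if adj.dtype != np.bool_ else adj
        xb = x.reshape(b, 1, n, f)
        wh = xb.matmul(self.W)                       # (B,K,N,F')
        src = wh.matmul(self.a_src)                  # (B,K,N,1)
        dst = wh.matmul(self.a_dst)                  # (B,K,N,1)
        e = (src + dst.transpose(0, 1, 3, 2)).leaky_relu(0.2)
        att = e.softmax(axis=-1, mask=mask[:, None, :, :])
        if self.edge_weight_mode == "multiply" and adj.dtype != np.bool_:
            w = constant(adj[:, None, :, :])
            att = att * w
            att = att / att.sum(axis=-1, keepdims=True)
        return att, wh

    def forward(self, x: Tensor, adj: np.ndarray) -> Tensor:
        b, n, _ = x.shape
        att, wh = self.attention(x, adj)
        h = att.matmul(wh)                           # (B,K,N,F')
        if self.b is not None:
            h = h + self.b
        if self.combine == "concat":
            h = self._act(h)
            return h.transpose(0, 2, 1, 3).reshape(b, n, self.heads * self.out_dim)
        h = h.mean(axis=1)                           # average heads first
        return self._act(h)


class GCNLayer:
    """Spectral graph convolution, first-order or Chebyshev.

    First-order: h' = act(D^{-1/2} A D^{-1/2} h W) with self-loops already
    present in A.  Chebyshev of order r: h' = act(sum_k T_k(L~) h W_k)
    where L~ is the Laplacian rescaled to [-1, 1] (lambda_max ~ 2).
    """

    def __init__(self, in_dim: int, out_dim: int,
                 filter_type: str = "first_order", order: int = 3,
                 slope: float = 0.2,
                 rng: np.random.Generator | None = None):
        if filter_type not in ("first_order", "chebyshev"):
            raise ValueError(f"unknown filter {filter_type!r}")
        if filter_type == "chebyshev" and order < 1:
            raise ValueError("chebyshev order must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.filter_type, self.order, self.slope = filter_type, order, slope
        self.in_dim, self.out_dim = in_dim, out_dim
        n_terms = 1 if filter_type == "first_order" else order + 1
        self.W = [parameter((in_dim, out_dim), rng) for _ in range(n_terms)]

    @property
    def width(self) -> int:
        return self.out_dim

    def parameters(self) -> list[Tensor]:
        return list(self.W)

    @staticmethod
    def _normalized(adj: np.ndarray) -> np.ndarray:
        deg = adj.sum(axis=-1)
        bad = deg <= 0
        if bad.any():
            import logging
            logging.getLogger(__name__).warning(
                "zero-degree nodes under normalization; degree clamped to 1")
            deg = np.where(bad, 1.0, deg)
        d = 1.0 / np.sqrt(deg)
        return adj * d[..., :, None] * d[..., None, :]

    def forward(self, x: Tensor, adj: np.ndarray) -> Tensor:
        norm = self._normalized(adj)
        if self.filter_type == "first_order":
            out = constant(norm).matmul(x).matmul(self.W[0])
        else:
            # scaled Laplacian with lambda_max = 2: (I - norm) - I = -norm
            lap_scaled = -norm
            t_prev = x
            t_cur = constant(lap_scaled).matmul(x)
            out = t_prev.matmul(self.W[0]) + t_cur.matmul(self.W[1])
            for k in range(2, self.order + 1):
                t_next = constant(2.0 * lap_scaled).matmul(t_cur) - t_prev
                out = out + t_next.matmul(self.W[k])
                t_prev, t_cur = t_cur, t_next
        return out.leaky_relu(self.slope)


class DenseLayer:
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, bias: bool = True):
        rng = rng or np.random.default_rng(0)
        self.W = parameter((in_dim, out_dim), rng)
        self.b = parameter(np.zeros(out_dim)) if bias else None

    def parameters(self) -> list[Tensor]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: Tensor) -> Tensor:
        out = x.matmul(self.W)
        if self.b is not None:
            out = out + self.b
        return out


# ---------------------------------------------------------------------------
# readout heads
# ---------------------------------------------------------------------------

def attention_pool(h: Tensor, pool_weight: Tensor,
                   pool_bias: Tensor | None = None) -> Tensor:
    """Graph representation P_i = sigmoid(W^p h'_i [+ b]); shape (B, N)."""
    b, n, f = h.shape
    if pool_weight.shape != (f, 1):
        raise ValueError("pool weight width must match node representation")
    z = h.matmul(pool_weight).reshape(b, n)
    if pool_bias is not None:
        z = z + pool_bias
    return z.sigmoid()


def attention_predict(p: Tensor, pred_weight: Tensor) -> Tensor:
    """prob = sum_i A_i P_i with A = softmax(W^A P); shape (B,)."""
    n = p.shape[-1]
    if pred_weight.shape != (n, n):
        raise ValueError("prediction weight must be N x N")
    logits = p.matmul(pred_weight.transpose(1, 0))
    a = logits.softmax(axis=-1)
    return (a * p).sum(axis=-1)


def gat_average_predict(p: Tensor) -> Tensor:
    """Average-pooling head: prob = sum_i P_i / N.

    Computed as sum(P * 1/N) so it agrees bit-for-bit with the
    attention head in its uniform-weight (W^A = 0) limit.
    """
    n = p.shape[-1]
    return (p * (1.0 / n)).sum(axis=-1)


def learn_pool(y: Tensor, s: Tensor) -> Tensor:
    """Learned pooling Y_pool = S^T Y: (B,N,1) x (B,N,C) -> (B,1,C)."""
    if y.shape[-2] != s.shape[-2] or s.shape[-1] != 1:
        raise ValueError("assignment S must be N x 1 matching Y's N")
    return s.transpose(0, 2, 1).matmul(y)


# ---------------------------------------------------------------------------
# model / results classes
# ---------------------------------------------------------------------------

class GraphModelResults:
    """Fitted-model container: best parameters, history, prediction and
    evaluation helpers, and a ``summary()`` table."""

    def __init__(self, model: "BaseGraphModel", history: dict):
        self.model = model
        self.history = history
        self.n_epochs = history.get("n_epochs", 0)

    def predict_proba(self, graphs: list[GraphSample]) -> np.ndarray:
        return self.model.predict_proba(graphs)

    def predict(self, graphs: list[GraphSample],
                threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(graphs) >= threshold).astype(int)

    def evaluate(self, graphs: list[GraphSample]):
        from .training import compute_metrics
        y = np.array([g.label for g in graphs])
        return compute_metrics(y, self.predict_proba(graphs))

    def summary(self) -> str:
        lines = [f"{type(self.model).__name__} results",
                 f"  epochs trained : {self.n_epochs}",
                 f"  final train loss: {self.history['train_loss'][-1]:.4f}"
                 if self.history.get("train_loss") else "  (no training run)"]
        if self.history.get("val_error"):
            lines.append(f"  best val error : {min(self.history['val_error']):.4f}")
        return "\n".join(lines)


class BaseGraphModel:
    """Common plumbing: data binding, parameter handling, fitting."""

    loss_kind = "bce"  # or "ce2" for two-class softmax heads

    def __init__(self, graphs: list[GraphSample] | None = None,
                 labels=None, seed: int = 0):
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.graphs = graphs
        if graphs is not None:
            self.x, self.adj, self.y = graphs_to_arrays(graphs)
            if labels is not None:
                self.y = np.asarray(labels, dtype=float)
            self.n_nodes = self.x.shape[1]
            self.n_features = self.x.shape[2]

    # subclasses populate self._layers / extra params and implement forward
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """Probability of the positive class for a batch, shape (B,)."""
        raise NotImplementedError

    def loss(self, x: Tensor, mask: np.ndarray, y: np.ndarray) -> Tensor:
        return binary_cross_entropy(self.forward(x, mask), y)

    def predict_proba(self, graphs: list[GraphSample] | None = None
                      ) -> np.ndarray:
        if graphs is None:
            x, mask = self.x, self.adj
        else:
            x, mask, _ = graphs_to_arrays(graphs)
        return self.forward(constant(x), mask).data

    def get_params(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_params(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), values):
            p.data = v.copy()

    def fit(self, config=None, val_graphs: list[GraphSample] | None = None
            ) -> GraphModelResults:
        """Train on the bound data with Adam and early stopping on the
        validation error rate (if a validation set is given)."""
        from .training import TrainConfig, fit_model
        config = config or TrainConfig()
        history = fit_model(self, config, val_graphs=val_graphs)
        return GraphModelResults(self, history)


class _GATBackboneMixin:
    """Shared constructor for the two-GAT-layer node representation part."""

    def _build_backbone(self, n_features: int, heads, units,
                        final_activation: str, bias: bool,
                        edge_weight_mode: str = "none"):
        dims = [n_features]
        self._layers: list[GATLayer] = []
        for i, (k, u) in enumerate(zip(heads, units)):
            last = i == len(units) - 1
            layer = GATLayer(
                dims[-1], u, k,
                combine="average" if last else "concat",
                activation=final_activation if last else "leaky_relu",
                bias=bias, edge_weight_mode=edge_weight_mode, rng=self.rng)
            self._layers.append(layer)
            dims.append(layer.width)
        self.repr_width = dims[-1]

    def node_representation(self, x: Tensor, adj: np.ndarray) -> Tensor:
        h = x
        for layer in self._layers:
            h = layer.forward(h, adj)
        return h


class GAT2(BaseGraphModel, _GATBackboneMixin):
    """GAT backbone + attention pooling + attention-weighted prediction.

    Hidden attention layers use LeakyReLU; the final averaged layer uses
    the sigmoid that also defines the pooling map.  With ``pred_weight``
    zero the prediction head reduces exactly to GAT-average.
    """

    def __init__(self, graphs=None, labels=None, *, n_nodes=None,
                 n_features=None, heads=(5, 3), units=(24, 3),
                 final_activation: str = "leaky_relu", bias: bool = True,
                 pool_bias: bool = True, edge_weight_mode: str = "none",
                 seed: int = 0):
        super().__init__(graphs, labels, seed=seed)
        if graphs is None:
            self.n_nodes, self.n_features = n_nodes, n_features
        self._build_backbone(self.n_features, heads, units,
                             final_activation, bias, edge_weight_mode)
        self.pool_weight = parameter((self.repr_width, 1), self.rng)
        self.pool_bias = parameter(np.zeros(1)) if pool_bias else None
        self.pred_weight = parameter((self.n_nodes, self.n_nodes), self.rng)

    @classmethod
    def from_dataset(cls, dataset, **kwargs) -> "GAT2":
        return cls(dataset.graphs, **kwargs)

    def parameters(self) -> list[Tensor]:
        ps = []
        for layer in self._layers:
            ps.extend(layer.parameters())
        ps += [self.pool_weight]
        if self.pool_bias is not None:
            ps.append(self.pool_bias)
        return ps + [self.pred_weight]

    def graph_representation(self, x: Tensor, adj: np.ndarray) -> Tensor:
        return attention_pool(self.node_representation(x, adj),
                              self.pool_weight, self.pool_bias)

    def forward(self, x: Tensor, adj: np.ndarray) -> Tensor:
        return attention_predict(self.graph_representation(x, adj),
                                 self.pred_weight)


class GATAverage(BaseGraphModel, _GATBackboneMixin):
    """GAT backbone + average-pooling prediction (prob = mean P_i)."""

    def __init__(self, graphs=None, labels=None, *, n_nodes=None,
                 n_features=None, heads=(5, 3), units=(24, 3),
                 final_activation: str = "leaky_relu", bias: bool = True,
                 pool_bias: bool = True, edge_weight_mode: str = "none",
                 seed: int = 0):
        super().__init__(graphs, labels, seed=seed)
        if graphs is None:
            self.n_nodes, self.n_features = n_nodes, n_features
        self._build_backbone(self.n_features, heads, units,
                             final_activation, bias, edge_weight_mode)
        self.pool_weight = parameter((self.repr_width, 1), self.rng)
        self.pool_bias = parameter(np.zeros(1)) if pool_bias else None

    def parameters(self) -> list[Tensor]:
        ps = []
        for layer in self._layers:
            ps.extend(layer.parameters())
        ps += [self.pool_weight]
        if self.pool_bias is not None:
            ps.append(self.pool_bias)
        return ps

    def forward(self, x: Tensor, adj: np.ndarray) -> Tensor:
        p = attention_pool(self.node_representation(x, adj),
                           self.pool_weight, self.pool_bias)
        return gat_average_predict(p)


class GATFC(BaseGraphModel, _GATBackboneMixin):
    """GAT backbone + flattened dense softmax classifier (two classes)."""

    loss_kind = "ce2"

    def __init__(self, graphs=None, labels=None, *, n_nodes=None,
                 n_features=None, heads=(5, 3), units=(24, 3),
                 fc_units: int = 64, bias: bool = True, seed: int = 0):
        super().__init__(graphs, labels, seed=seed)
        if graphs is None:
            self.n_nodes, self.n_features = n_nodes, n_features
        self._build_backbone(self.n_features, heads, units,
                             "leaky_relu", bias)
        flat = self.n_nodes * self.repr_width
        self.fc1 = DenseLayer(flat, fc_units, rng=self.rng)
        self.fc2 = DenseLayer(fc_units, 2, rng=self.rng)

    def parameters(self) -> list[Tensor]:
        ps = []
        for layer in self._layers:
            ps.extend(layer.parameters())
        return ps + self.fc1.parameters() + self.fc2.parameters()

    def class_probabilities(self, x: Tensor, mask: np.ndarray) -> Tensor:
        h = self.node_representation(x, mask)
        b = h.shape[0]
        flat = h.reshape(b, h.shape[1] * h.shape[2])
        hidden = self.fc1.forward(flat).leaky_relu(0.2)
        return self.fc2.forward(hidden).softmax(axis=-1)

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        return self.class_probabilities(x, mask)[:, 1]

    def loss(self, x: Tensor, mask: np.ndarray, y: np.ndarray) -> Tensor:
        probs = self.class_probabilities(x, mask)
        p = probs * (1.0 - 2.0 * _EPS) + _EPS
        onehot = np.stack([1.0 - y, y], axis=-1)
        return -(constant(onehot) * p.log()).sum(axis=-1).mean()


class GATLearn(BaseGraphModel, _GATBackboneMixin):
    """GAT backbone + learned cluster-assignment pooling (Y_pool = S^T Y).

    Two separate dense paths produce an N x 11 feature map and an N x 1
    assignment vector; their product feeds a final dense sigmoid unit.
    The internals of the two paths are only loosely constrained by shape,
    so this head is minimal and considered experimental.
    """

    def __init__(self, graphs=None, labels=None, *, n_nodes=None,
                 n_features=None, heads=(5, 3), units=(24, 3),
                 pooled_width: int = 11, bias: bool = True, seed: int = 0):
        super().__init__(graphs, labels, seed=seed)
        if graphs is None:
            self.n_nodes, self.n_features = n_nodes, n_features
        self._build_backbone(self.n_features, heads, units,
                             "leaky_relu", bias)
        self.feature_path = DenseLayer(self.repr_width, pooled_width,
                                       rng=self.rng)
        self.assign_path = DenseLayer(self.repr_width, 1, rng=self.rng)
        self.fc = DenseLayer(pooled_width, 1, rng=self.rng)

    def parameters(self) -> list[Tensor]:
        ps = []
        for layer in self._layers:
            ps.extend(layer.parameters())
        return (ps + self.feature_path.parameters()
                + self.assign_path.parameters() + self.fc.parameters())

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        h = self.node_representation(x, mask)
        y_map = self.feature_path.forward(h).leaky_relu(0.2)   # (B,N,11)
        s = self.assign_path.forward(h).softmax(axis=-2)        # (B,N,1)
        pooled = learn_pool(y_map, s)                           # (B,1,11)
        b = pooled.shape[0]
        return self.fc.forward(pooled.reshape(b, -1)).sigmoid().reshape(b)


class GCNAttention(BaseGraphModel):
    """One spectral convolution layer feeding the attention pooling and
    prediction part of GAT2 (the GCN-at comparison models)."""

    def __init__(self, graphs=None, labels=None, *, n_nodes=None,
                 n_features=None, units: int = 24,
                 filter_type: str = "first_order", order: int = 3,
                 pool_bias: bool = True, seed: int = 0):
        super().__init__(graphs, labels, seed=seed)
        if graphs is None:
            self.n_nodes, self.n_features = n_nodes, n_features
        self.gcn = GCNLayer(self.n_features, units, filter_type=filter_type,
                            order=order, rng=self.rng)
        self.pool_weight = parameter((units, 1), self.rng)
        self.pool_bias = parameter(np.zeros(1)) if pool_bias else None
        self.pred_weight = parameter((self.n_nodes, self.n_nodes), self.rng)

    def parameters(self) -> list[Tensor]:
        ps = self.gcn.parameters() + [self.pool_weight]
        if self.pool_bias is not None:
            ps.append(self.pool_bias)
        return ps + [self.pred_weight]

    def forward(self, x: Tensor, adj: np.ndarray) -> Tensor:
        h = self.gcn.forward(x, adj.astype(float))
        p = attention_pool(h, self.pool_weight, self.pool_bias)
        return attention_predict(p, self.pred_weight)
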