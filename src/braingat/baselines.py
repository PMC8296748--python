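"""Non-graph comparison classifiers under the same fold splits.

SVM (linear kernel, C=1), PCA+SVM (99% retained variance), and random
forest come from scikit-learn; the MLP (two hidden layers with dropout)
and the small CNN (three 3x3 convolution layers + two dense layers) run
on the package's own autodiff engine so their reference configurations
(dropout rate, per-layer kernel counts, learning rates) can be honored
exactly.  All flattened-feature models consume the strictly-upper-
triangular connectivity values; the CNN sees the full matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.svm import SVC

from .graphs import GraphSample, flatten_upper_triangle
from .synthetic import split_folds
from .tensor import Tensor, constant, parameter
from .training import (Adam, EvaluationReport, TrainConfig, compute_metrics)

logger = logging.getLogger(__name__)

__all__ = ["BaselineConfig", "run_baseline", "MLPNet", "CNNNet"]

BASELINE_NAMES = ("svm", "pca_svm", "rf", "mlp", "cnn")


@dataclass(frozen=True)
class BaselineConfig:
    svm_c: float = 1.0
    pca_variance: float = 0.99
    rf_trees: int = 300
    rf_depth: int = 30
    mlp_units: tuple[int, int] = (64, 32)
    mlp_dropout: float = 0.5
    mlp_learning_rate: float = 5e-4
    cnn_kernels: tuple[int, int, int] = (32, 64, 128)
    cnn_fc_units: int = 1024
    cnn_learning_rate: float = 1e-4

    @classmethod
    def synthetic_defaults(cls) -> "BaselineConfig":
        """Hyperparameters of the 30-node synthetic benchmark."""
        return cls(rf_trees=128, rf_depth=20, cnn_kernels=(16, 32, 64))


# ---------------------------------------------------------------------------
# autodiff-backed nets
# ---------------------------------------------------------------------------

class MLPNet:
    """Two LeakyReLU hidden layers with dropout, one sigmoid output."""

    def __init__(self, in_dim: int, units=(64, 32), dropout: float = 0.5,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dropout = dropout
        self.rng = rng
        dims = [in_dim, *units]
        self.W = [parameter((dims[i], dims[i + 1]), rng)
                  for i in range(len(units))]
        self.b = [parameter(np.zeros(u)) for u in units]
        self.w_out = parameter((dims[-1], 1), rng)
        self.b_out = parameter(np.zeros(1))

    def parameters(self):
        return [*self.W, *self.b, self.w_out, self.b_out]

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        h = x
        for w, b in zip(self.W, self.b):
            h = (h.matmul(w) + b).leaky_relu(0.2)
            if training and self.dropout > 0:
                keep = (self.rng.random(h.shape) >= self.dropout)
                h = h * constant(keep / (1.0 - self.dropout))
        return (h.matmul(self.w_out) + self.b_out).reshape(h.shape[0]).sigmoid()

    def loss(self, x: Tensor, y: np.ndarray) -> Tensor:
        from .models import binary_cross_entropy
        return binary_cross_entropy(self.forward(x, training=True), y)


def _conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid-padding stride-1 convolution.

    ``x`` is (B, C, H, W); ``w`` is (KH, KW, C, O).  Implemented as a sum
    of shifted slices, each a matmul over channels.
    """
    _, _, h, wd = x.shape
    kh, kw = w.shape[0], w.shape[1]
    ho, wo = h - kh + 1, wd - kw + 1
    out = None
    for di in range(kh):
        for dj in range(kw):
            patch = x[:, :, di:di + ho, dj:dj + wo]       # (B,C,Ho,Wo)
            term = patch.transpose(0, 2, 3, 1).matmul(w[di, dj])
            out = term if out is None else out + term
    out = out + b
    return out.transpose(0, 3, 1, 2)                       # (B,O,Ho,Wo)


class CNNNet:
    """Three 3x3 ReLU convolution layers and two dense layers (softmax
    over two classes)."""

    def __init__(self, side: int, kernels=(32, 64, 128), fc_units: int = 1024,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        chans = [1, *kernels]
        self.conv_w = [parameter(rng.uniform(
            -np.sqrt(1.0 / (9 * chans[i])), np.sqrt(1.0 / (9 * chans[i])),
            size=(3, 3, chans[i], chans[i + 1]))) for i in range(3)]
        self.conv_b = [parameter(np.zeros(c)) for c in kernels]
        out_side = side - 6          # three valid 3x3 convolutions
        if out_side < 1:
            raise ValueError(f"input side {side} too small for 3 conv layers")
        flat = kernels[-1] * out_side * out_side
        self.fc1 = parameter((flat, fc_units), rng)
        self.fc1_b = parameter(np.zeros(fc_units))
        self.fc2 = parameter((fc_units, 2), rng)
        self.fc2_b = parameter(np.zeros(2))

    def parameters(self):
        return [*self.conv_w, *self.conv_b,
                self.fc1, self.fc1_b, self.fc2, self.fc2_b]

    def class_probabilities(self, x: Tensor) -> Tensor:
        b = x.shape[0]
        h = x.reshape(b, 1, x.shape[1], x.shape[2])
        for w, bias in zip(self.conv_w, self.conv_b):
            h = _conv2d(h, w, bias).relu()
        flat = h.reshape(b, int(np.prod(h.shape[1:])))
        hidden = (flat.matmul(self.fc1) + self.fc1_b).relu()
        return (hidden.matmul(self.fc2) + self.fc2_b).softmax(axis=-1)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        return self.class_probabilities(x)[:, 1]

    def loss(self, x: Tensor, y: np.ndarray) -> Tensor:
        eps = 1e-12
        p = self.class_probabilities(x) * (1 - 2 * eps) + eps
        onehot = np.stack([1.0 - y, y], axis=-1)
        return -(constant(onehot) * p.log()).sum(axis=-1).mean()


def _fit_net(net, x: np.ndarray, y: np.ndarray,
             val: tuple[np.ndarray, np.ndarray],
             lr: float, config: TrainConfig) -> None:
    """Adam training with early stopping on validation error rate."""
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.parameters(), lr=lr)
    vx, vy = val
    best_err, best, since = np.inf, None, 0
    n = x.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            loss = net.loss(constant(x[idx]), y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite baseline loss")
            loss.backward()
            opt.step()
        probs = net.forward(constant(vx)).data
        err = float(np.mean((probs >= 0.5) != vy))
        if err < best_err - 1e-12:
            best_err, since = err, 0
            best = [p.data.copy() for p in net.parameters()]
        else:
            since += 1
            if since >= config.patience:
                break
    if best is not None:
        for p, v in zip(net.parameters(), best):
            p.data = v.copy()


# ---------------------------------------------------------------------------
# harness
# ---------------------------------------------------------------------------

def _flat_features(graphs: list[GraphSample]) -> np.ndarray:
    return np.stack([flatten_upper_triangle(g.node_features) for g in graphs])


def run_baseline(name: str, graphs: list[GraphSample],
                 baseline_config: BaselineConfig | None = None,
                 train_config: TrainConfig | None = None) -> EvaluationReport:
    """Cross-validate one named baseline under the shared fold splits."""
    if name not in BASELINE_NAMES:
        raise ValueError(f"unknown baseline {name!r}; choose from "
                         f"{BASELINE_NAMES}")
    bc = baseline_config or BaselineConfig()
    tc = train_config or TrainConfig()
    y_all = np.array([g.label for g in graphs], dtype=float)
    if name == "cnn":
        x_all = np.stack([g.node_features for g in graphs])
    else:
        x_all = _flat_features(graphs)

    folds = split_folds(len(graphs), tc.folds, seed=tc.seed)
    report = EvaluationReport(model_name=name,
                              config_echo={**asdict(bc), **asdict(tc)})
    for f, (tr, te) in enumerate(folds):
        xtr, ytr, xte, yte = x_all[tr], y_all[tr], x_all[te], y_all[te]
        if name == "svm":
            est = SVC(kernel="linear", C=bc.svm_c)
            est.fit(xtr, ytr)
            scores = est.decision_function(xte)
        elif name == "pca_svm":
            est = make_pipeline(PCA(n_components=bc.pca_variance,
                                    random_state=tc.seed),
                                SVC(kernel="linear", C=bc.svm_c))
            est.fit(xtr, ytr)
            scores = est.decision_function(xte)
        elif name == "rf":
            est = RandomForestClassifier(n_estimators=bc.rf_trees,
                                         max_depth=bc.rf_depth,
                                         random_state=tc.seed + f)
            est.fit(xtr, ytr)
            scores = est.predict_proba(xte)[:, 1]
        elif name == "mlp":
            net = MLPNet(xtr.shape[1], units=bc.mlp_units,
                         dropout=bc.mlp_dropout, seed=tc.seed + f)
            _fit_net(net, xtr, ytr, (xte, yte), bc.mlp_learning_rate, tc)
            scores = net.forward(constant(xte)).data
        else:  # cnn
            net = CNNNet(xtr.shape[1], kernels=bc.cnn_kernels,
                         fc_units=bc.cnn_fc_units, seed=tc.seed + f)
            _fit_net(net, xtr, ytr, (xte, yte), bc.cnn_learning_rate, tc)
            scores = net.forward(constant(xte)).data
        if name in ("svm", "pca_svm"):
            preds = (scores >= 0.0).astype(int)
            from .training import confusion_counts, metrics_from_counts, auc_score
            row = metrics_from_counts(confusion_counts(yte, preds),
                                      auc=auc_score(yte, scores))
        else:
            row = compute_metrics(yte, scores)
        report.rows.append(row)
        logger.info("%s fold %d: accuracy %.4f", name, f, row.accuracy)
    return report
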