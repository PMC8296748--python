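"""Interpreting a trained graph classifier by feature importance.

Two attribution routes over the node-feature matrix (N nodes x F
features):

* a *learned feature mask* in [0,1]^(N x F), shared across samples,
  optimized so the model still classifies the masked features correctly
  while L1 and entropy penalties push unimportant entries toward 0
  (the mask-learning idea behind GNNExplainer);
* *gradient saliency*: the gradient of the model loss w.r.t. the input
  features, averaged across samples first and then taken in absolute
  value.

Explanations are evaluated by *feature hacking*: zero the top-k ranked
feature entries of every sample and measure the change of prediction
probability (CPP), the number of label-changed instances (NLCI), and the
full metric bundle after perturbation.  Top-ranked connections are
summarized by group means and an independent two-sample t test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .graphs import GraphSample
from .models import BaseGraphModel, graphs_to_arrays
from .tensor import Tensor, constant, parameter
from .training import Adam, MetricsRow, compute_metrics

logger = logging.getLogger(__name__)

__all__ = [
    "MaskConfig", "FeatureMask", "FeatureRanking", "PerturbationReport",
    "learn_feature_mask", "saliency", "random_ranking",
    "hack_features", "perturb_evaluate", "analyze_top_connections",
]


@dataclass(frozen=True)
class MaskConfig:
    learning_rate: float = 1e-2
    steps: int = 200
    l1_coef: float = 0.005
    entropy_coef: float = 0.1
    target: str = "predicted"  # or "true"
    init_logit: float = 1.0
    init_noise: float = 0.01
    seed: int = 0


@dataclass
class FeatureRanking:
    """Ordered (node, feature, score) triples, scores non-increasing.

    Ties are broken deterministically by (score desc, node idx, feature
    idx)."""

    entries: list[tuple[int, int, float]]

    @classmethod
    def from_scores(cls, scores: np.ndarray) -> "FeatureRanking":
        n, f = scores.shape
        nodes, feats = np.divmod(np.arange(n * f), f)
        flat = scores.ravel()
        order = np.lexsort((feats, nodes, -flat))
        return cls([(int(nodes[i]), int(feats[i]), float(flat[i]))
                    for i in order])

    def top(self, k: int) -> list[tuple[int, int]]:
        return [(n, f) for n, f, _ in self.entries[:k]]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries,
                            columns=["node", "feature", "score"])


@dataclass
class FeatureMask:
    """Global N x F importance mask with entries in [0, 1]."""

    values: np.ndarray
    history: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("mask entries must lie in [0, 1]")

    def ranking(self) -> FeatureRanking:
        return FeatureRanking.from_scores(self.values)

    def connection_scores(self) -> np.ndarray:
        """Symmetrized scores: average of the (i,j) and (j,i) entries."""
        return (self.values + self.values.T) / 2.0


@dataclass
class PerturbationReport:
    k: int
    cpp: float
    nlci: int
    metrics_after: MetricsRow

    def as_dict(self) -> dict:
        return {"k": self.k, "cpp": self.cpp, "nlci": self.nlci,
                "metrics_after": self.metrics_after.as_dict()}


def _entropy(m: Tensor) -> Tensor:
    eps = 1e-12
    mm = m * (1.0 - 2.0 * eps) + eps
    return -(mm * mm.log() + (1.0 - mm) * (1.0 - mm).log())


def learn_feature_mask(model: BaseGraphModel, graphs: list[GraphSample],
                       config: MaskConfig | None = None) -> FeatureMask:
    """Learn one sigmoid-parameterized mask shared by all ``graphs``.

    The objective is the model's classification loss on mask * features
    (targets = the model's own unmasked predictions by default, or the
    true labels) plus an L1 penalty and an entropy penalty pushing
    entries toward {0, 1}.  Model parameters stay frozen; only the mask
    logits are optimized.
    """
    config = config or MaskConfig()
    x, adj_mask, y_true = graphs_to_arrays(graphs)
    n, f = x.shape[1], x.shape[2]
    rng = np.random.default_rng(config.seed)

    if config.target == "predicted":
        base = model.forward(constant(x), adj_mask).data
        target = (base >= 0.5).astype(float)
    elif config.target == "true":
        target = y_true
    else:
        raise ValueError(f"unknown mask target {config.target!r}")

    logits = parameter(config.init_logit
                       + config.init_noise * rng.standard_normal((n, f)))
    opt = Adam([logits], lr=config.learning_rate)
    history = {"loss": []}
    from .models import binary_cross_entropy
    for _ in range(config.steps):
        opt.zero_grad()
        for p in model.parameters():
            p.zero_grad()
        m = logits.sigmoid()
        masked = constant(x) * m.reshape(1, n, f)
        prob = model.forward(masked, adj_mask)
        loss = binary_cross_entropy(prob, target)
        if config.l1_coef:
            loss = loss + config.l1_coef * m.mean()
        if config.entropy_coef:
            loss = loss + config.entropy_coef * _entropy(m).mean()
        if not np.isfinite(loss.data):
            raise FloatingPointError("non-finite mask-learning loss")
        loss.backward()
        opt.step()
        history["loss"].append(loss.item())
    values = 1.0 / (1.0 + np.exp(-logits.data))
    return FeatureMask(values=values, history=history)


def saliency(model: BaseGraphModel, graphs: list[GraphSample],
             absolute_first: bool = False) -> FeatureRanking:
    """Gradient saliency of the model loss w.r.t. the input features.

    Per-feature score = |mean over samples of d(loss)/d(feature)|
    (average first, then absolute value).  ``absolute_first=True``
    averages |gradients| instead.
    """
    x, adj_mask, y = graphs_to_arrays(graphs)
    xt = Tensor(x, requires_grad=True)
    for p in model.parameters():
        p.zero_grad()
    loss = model.loss(xt, adj_mask, y)
    loss.backward()
    grads = xt.grad  # (B, N, F), scaled by 1/B through the mean loss
    if absolute_first:
        scores = np.abs(grads).mean(axis=0)
    else:
        scores = np.abs(grads.mean(axis=0))
    return FeatureRanking.from_scores(scores)


def random_ranking(n_nodes: int, n_features: int, seed: int = 0
                   ) -> FeatureRanking:
    """Uniformly random feature order (the null explanation baseline)."""
    rng = np.random.default_rng(seed)
    scores = rng.random((n_nodes, n_features))
    return FeatureRanking.from_scores(scores)


def hack_features(graphs: list[GraphSample], ranking: FeatureRanking,
                  k: int) -> list[GraphSample]:
    """Zero the top-k ranked (node, feature) entries of every sample.

    Pure function: adjacency and the input graphs are untouched.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds number of features {len(ranking)}")
    top = ranking.top(k)
    out = []
    for g in graphs:
        feats = g.node_features.copy()
        for i, j in top:
            feats[i, j] = 0.0
        out.append(replace(g, node_features=feats,
                           adj_weights=g.adj_weights.copy()))
    return out


def perturb_evaluate(model: BaseGraphModel, graphs: list[GraphSample],
                     ranking: FeatureRanking,
                     ks: list[int]) -> list[PerturbationReport]:
    """Feature-hacking evaluation of an explanation.

    For each k: CPP = mean |prob_before - prob_after|; NLCI = number of
    samples whose 0.5-thresholded label flips; plus the metric bundle on
    the perturbed samples.
    """
    y = np.array([g.label for g in graphs])
    before = model.predict_proba(graphs)
    out = []
    for k in ks:
        after = model.predict_proba(hack_features(graphs, ranking, k))
        cpp = float(np.mean(np.abs(before - after)))
        nlci = int(np.sum((before >= 0.5) != (after >= 0.5)))
        out.append(PerturbationReport(
            k=k, cpp=cpp, nlci=nlci,
            metrics_after=compute_metrics(y, after)))
    return out


def _welch_or_student(a: np.ndarray, b: np.ndarray, welch: bool) -> float:
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if a.std() == 0 and b.std() == 0:
        # degenerate variances: identical constants vs distinct constants
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


def analyze_top_connections(graphs: list[GraphSample],
                            ranking: FeatureRanking, top_n: int,
                            welch: bool = True) -> pd.DataFrame:
    """Group statistics of the top-ranked connections.

    Symmetric duplicates (i,j)/(j,i) collapse to a single connection.
    Columns: node_i, node_j, positive/negative group means of the signed
    feature value, mean difference, and the two-sample t-test p value
    (Welch by default).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    labels = np.array([g.label for g in graphs])
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes for group comparison")
    feats = np.stack([g.node_features for g in graphs])

    seen: set[tuple[int, int]] = set()
    records = []
    for i, j, score in ranking.entries:
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        vals = (feats[:, i, j] + feats[:, j, i]) / 2.0
        pos, neg = vals[labels == 1], vals[labels == 0]
        records.append({
            "node_i": key[0], "node_j": key[1], "score": score,
            "mean_positive": float(pos.mean()),
            "mean_negative": float(neg.mean()),
            "mean_difference": float(pos.mean() - neg.mean()),
            "p_value": _welch_or_student(pos, neg, welch)})
        if len(records) == top_n:
            break
    return pd.DataFrame(records)
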