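# braingat

Graph attention networks for classifying weighted functional brain
networks, with an interpretation stage that ranks node-feature importance
and measures explanation fidelity by feature perturbation.

## The problem

Resting-state fMRI yields, for each subject, an N×N functional
connectivity matrix S of Pearson correlations ρ between the mean time
series of N brain regions (ROIs). Treating regions as nodes, |ρ| as edge
weights and each region's signed connectivity profile h_i = (ρ_{i1}, …,
ρ_{iN}) as its node features turns diagnosis (e.g. autism spectrum
disorder vs. healthy control) into binary graph classification. The
package implements:

* **GAT2** — a two-layer multi-head graph attention network with a
  learned attention readout. Attention coefficients over the structural
  neighborhood N_i:

      a_ij = softmax_{j∈N_i}( LeakyReLU( aᵀ [W h_i ∥ W h_j] ) )

  Hidden layers concatenate K head outputs, the final layer averages
  them. The readout maps each node to a scalar P_i = σ(Wᵖ h′_i), forms
  node weights A = softmax(W^A P), and predicts
  prob = Σ_i A_i P_i ∈ (0,1), trained with binary cross-entropy.
* **Comparison models** — GAT-average (prob = Σ P_i / N), GAT-fc
  (flattened node representations into a dense softmax), GAT-learn
  (learned cluster-assignment pooling Y_pool = Sᵀ Y), GCN-at with
  first-order or Chebyshev spectral filters, and SVM / PCA+SVM / random
  forest / MLP / CNN baselines on flattened upper-triangle features.
* **Evaluation** — fivefold cross-validation with early stopping
  (patience 15 on the held-out fold's error rate), reporting accuracy,
  sensitivity, specificity, F1, AUC (rank formulation with midrank
  ties) and Matthews correlation, as mean ± std across folds.
* **Interpretation** — a learned global feature mask in [0,1]^{N×F}
  (GNNExplainer-style: classification loss on mask⊙features plus L1 and
  entropy penalties) and gradient saliency (|mean over samples of
  ∂loss/∂feature|). Explanations are scored by *feature hacking*:
  zeroing the top-k ranked features and measuring the change of
  prediction probability (CPP), the number of label-changed instances
  (NLCI) and the metric deltas; top connections are summarized with
  group means and two-sample t tests.
* **Synthetic benchmark** — 4000 complete 30-node graphs with
  uniform(0,1) weights; a fixed random subset of 15 nodes defines
  W1 (within-subset weight sum) and W2 (subset-to-rest sum), and a graph
  is Class-one iff W0 = 2·W1 + W2 exceeds the dataset mean of W0. This
  fully specified generator makes every stage testable without any
  neuroimaging download.

All differentiable models run on a compact reverse-mode autodiff engine
over numpy arrays (`braingat.tensor`), verified against finite
differences in the test suite.

## Worked example

```python
import numpy as np
from braingat import (GAT2, SyntheticSpec, TrainConfig,
                      generate_synthetic_dataset, split_folds)
from braingat.training import compute_metrics, fit_model

ds = generate_synthetic_dataset(SyntheticSpec(n_graphs=500, n_nodes=30,
                                              n_selected=15, seed=0))
train_idx, test_idx = split_folds(len(ds), 5, seed=0)[0]
train = [ds.graphs[i] for i in train_idx]
test = [ds.graphs[i] for i in test_idx]

model = GAT2(train, heads=(4, 4), units=(16, 16), seed=0)
fit_model(model, TrainConfig(max_epochs=80, seed=0, learning_rate=5e-4),
          val_graphs=test)
row = compute_metrics(np.array([g.label for g in test]),
                      model.predict_proba(test))
print(f"accuracy {row.accuracy:.3f}  F1 {row.f1:.3f}  AUC {row.auc:.3f}")
```

Output:

```
accuracy 0.730  F1 0.716  AUC 0.775
```

At this deliberately small scale (500 graphs, 80 epochs) the model is
well above chance; at the full benchmark scale (4000 graphs, early
stopping with patience 15, typically ~300 epochs) one fold reaches
accuracy ≈ 0.95 (see below). The same `GAT2` object exposes the
interpretation stage:

```python
from braingat import MaskConfig, learn_feature_mask, perturb_evaluate

mask = learn_feature_mask(model, test, MaskConfig(steps=120, seed=0))
reports = perturb_evaluate(model, test, mask.ranking(), ks=[0, 45, 90])
for r in reports:
    print(f"k={r.k:3d}  CPP={r.cpp:.3f}  NLCI={r.nlci}  "
          f"accuracy={r.metrics_after.accuracy:.3f}")
```

```
k=  0  CPP=0.000  NLCI=0  accuracy=0.730
k= 45  CPP=0.015  NLCI=10  accuracy=0.710
k= 90  CPP=0.032  NLCI=29  accuracy=0.560
```

Zeroing the top-ranked features steadily flips predictions and erodes
accuracy — the fidelity signal used to compare explanation methods.

A command-line interface mirrors the library
(`braingat simulate|construct|train|baseline|evaluate|explain|perturb`);
see `braingat --help`.

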