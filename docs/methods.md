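# Methods

## Graph construction

A subject is summarized by the N×N Pearson matrix of their ROI mean time
series. Edge weights are |ρ| — connectivity strength regardless of sign —
while node features keep the signed rows, so thresholding changes the
graph's structure but never the feature content. Thresholding uses a
strict inequality (an edge survives iff |ρ| > t), and the unit diagonal
counts as a self-loop edge, so a dense N-node network has N² adjacency
entries (12,100 at N = 110) and node i always belongs to its own
neighborhood. Sparsity is reported as the zeroed fraction of those N²
entries. A constant (zero-variance) ROI has undefined correlations;
its off-diagonal entries are set to 0 with a logged warning rather than
aborting a batch, since one flat region should not invalidate a subject.

## The GAT2 model

Two masked multi-head attention layers learn node representations; a
learned readout produces the graph-level prediction. The attention
softmax runs over the structural neighborhood only; on a dense network
that is every node. Hidden layers concatenate head outputs after a
LeakyReLU (slope 0.2); the final layer averages heads. The readout is
P_i = σ(Wᵖ h′_i + b), A = softmax(W^A P), prob = Σ A_i P_i — a convex
combination of per-node sigmoids, so prob is always a valid probability
without a separate output squashing. Setting W^A = 0 makes A uniform and
recovers the average-pooling comparison head exactly (this identity is
asserted bitwise in the tests).

Three implementation choices deserve justification:

* **Final-layer activation.** We use LeakyReLU after the averaged final
  attention layer, reserving the sigmoid for the pooling map. The
  alternative (sigmoid also on the final layer, `final_activation=
  "sigmoid"`) stacks two saturating squashes between the aggregated
  signal and the loss; on the synthetic benchmark this demonstrably caps
  accuracy around 85% because the graph-level discriminant — a small
  fluctuation on a large mean — cannot pass two saturations with
  bias-free layers at practical learning rates.
* **Biases.** Attention layers carry a per-unit additive bias and the
  pooling sigmoid a scalar bias (both default on, both configurable
  off). The class boundary of the synthetic benchmark sits at the
  dataset mean of a weight functional whose scale is ~30× its standard
  deviation; without biases the network must synthesize that offset from
  cancelling weight combinations, which Adam at lr 1e-4 does not find
  within realistic epoch budgets.
* **Attention initialization.** The attention vectors a are initialized
  at 5% of the fan-based scale used for the weight matrices, so the
  initial attention is near-uniform and the layers begin as stable mean
  aggregators. Large random initial attention injects feature-dependent
  aggregation noise that measurably decorrelates the learned score from
  the class signal. The sharpening of attention is then driven by the
  data, not by the initialization.

An optional mode multiplies the attention coefficients by the edge
weights (renormalized) for weighted aggregation experiments; it is off
by default and not needed for any reported result.

## Training and evaluation protocol

Adam (lr 1e-4 for graph models, 5e-4 for the MLP), batch size 10,
fivefold cross-validation. Early stopping follows the protocol of
monitoring the held-out fold: training stops when the fold's error rate
has not improved for 15 consecutive epochs, and the best-epoch
parameters are restored. Monitoring the evaluation fold is a
faithfulness choice, not methodological advice; pass a separate
validation set to `fit_model` for nested validation. Metrics come from
the standard confusion-matrix formulas; MCC with a zero denominator is
reported as 0 (its undefined limit); AUC uses the Mann-Whitney rank
formulation with midrank ties, which the tests verify equals the
trapezoidal ROC area. Maximum epochs default to 500.

## Synthetic benchmark

The generator emulates a fully specified graph-classification study:
4000 complete 30-node graphs, i.i.d. uniform(0,1) edge weights, one
seeded 15-node subset fixed for the whole dataset, label = [W0 > mean
W0] with W0 = 2·W1 + W2. Labeling is two-pass (all W0 first, then the
mean), and ties go to Class-two per the strict inequality. The subset is
drawn once per dataset: with per-graph subsets the label would not be a
function of the observable graph and no classifier could beat chance.
Node features are the weight-matrix rows with unit diagonal, mirroring
the brain-network construction; graphs are fed dense.

What the generator does *not* emulate: signed correlations, the
dependence structure of real functional connectivity, site/protocol
heterogeneity, and class-conditional covariance differences. Passing the
benchmark demonstrates that the models and the training loop learn a
planted linear-functional signal at the reference operating point — not
that they would achieve any particular accuracy on clinical data.

Because the weight matrix is symmetric, W0 equals Σ_j Σ_{k∈S} w_jk — a
node-uniform linear functional of each node's feature row. The benchmark
is therefore linearly separable given the subset, which is why a linear
SVM scores ~0.92 and why within-subset entries (counted in both
orientations) should dominate a faithful feature-importance map.

## Interpretation stage

The feature mask is a single N×F sigmoid-parameterized matrix shared by
all provided samples, optimized for 200 steps (lr 1e-2) against the
model's classification loss on mask⊙features — by default with the
model's own predictions as targets, so the mask explains the model
rather than the labels — plus an L1 penalty (0.005) shrinking
unimportant entries and an entropy penalty (0.1) pushing entries toward
{0, 1}. The mask is initialized near 1 (pre-squash logit 1.0 + small
noise) so the identity mask is recoverable when the penalties are zero.

Saliency scores are |mean over samples of ∂loss/∂feature| — average
first, then absolute value, in that order; the absolute-first variant is
available behind a flag. Feature hacking zeroes exactly the top-k ranked
(node, feature) entries in every sample, leaving the adjacency and the
original objects untouched; CPP is the mean absolute probability change
and NLCI the count of flipped 0.5-thresholded labels. Connection-level
summaries average the (i,j) and (j,i) mask entries, collapse symmetric
duplicates, and use Welch's two-sample t test by default (pooled-variance
Student's t behind a flag). Degenerate cases are pinned down: identical
constant groups give p = 1, distinct constant groups p = 0, groups with
fewer than two samples report an undefined (NaN) p.

## Numerical and engineering choices

All differentiable models run on a minimal reverse-mode autodiff engine
over float64 numpy arrays; gradients are validated against central
finite differences (relative tolerance 1e-4 at LeakyReLU kinks, far
tighter elsewhere). Forward passes agree with explicit-loop oracles to
1e-10 on small graphs. Weight matrices use scaled-uniform fan-based
initialization from a seeded generator; every source of randomness in a
run derives from one seed, and identical seeds give bit-identical
reports. CSV round trips are lossless (17-significant-digit output,
round-trip float parsing). Connectivity files are validated on read:
NaNs, out-of-range values and asymmetries beyond 1e-8 are rejected with
locations; asymmetries within tolerance are symmetrized by averaging.

## Problem sizes used in the shipped checks

The shipped acceptance run trains GAT2 on one fold of the fivefold split
of the full 4000-graph benchmark (early stopping typically triggers near
epoch 300), and the SVM/random-forest baselines on all five folds; the
explanation-fidelity checks aggregate five seeds of a 500-graph variant
with a smaller GAT2 (2+2 heads, 8+8 units, 80 epochs). These sizes were
chosen so the whole pipeline — generation, training, explanation,
perturbation — is exercised end to end at desk scale; single-fold GAT2
accuracy varies by roughly ±1 point across seeds at the full scale.

## Known limitations

* The ABIDE-scale experiments (110-node networks, 1035 subjects) are out
  of scope for reproduction here; the brain-network pathway is exercised
  on synthetic correlation matrices and small fixtures only.
* GAT-learn's two internal paths are only shape-constrained by their
  description; our minimal realization is flagged experimental.
* Early stopping on the evaluation fold (the reference protocol) optimistically
  biases fold metrics; the nested-validation mode exists but is not the
  default.
* The CNN baseline is faithful to its reference architecture but slow on
  CPU at full scale; it is exercised at reduced sizes in the tests.
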