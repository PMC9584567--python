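# Methods

## Problem

Co-administered drugs interact through many distinct pharmacological
mechanisms ("events": metabolism decreased, serum concentration increased,
…).  Given per-drug binary descriptor profiles in three categories
(chemical substructure, target, enzyme) and a set of drug pairs labeled
with one of C event types, the task is multiclass classification of the
event type of a drug pair — including pairs involving drugs with no known
interactions at all (cold start).

## Model

**Features.** Within each category, drug similarity is the Jaccard index
of the two descriptor bit sets.  A drug's feature vector is its similarity
profile to all N drugs, concatenated across the three categories:
X ∈ R^{N×3N}.  Two conventions cover degenerate inputs: an all-zero
descriptor row gets similarity 0 to every other drug and 1 to itself, and
the diagonal self-similarity columns are kept in X as ordinary features.

**Views.** Three symmetric graphs over the drug set:

* *adjacency* A_adj — binary, edge iff a labeled pair exists (any event
  type);
* *diffusion* A_diff = α (I − (1−α) D̃^{-1/2} Ã D̃^{-1/2})^{-1} — the
  Personalized PageRank of the adjacency (restart probability α, default
  0.15), computed by an exact dense linear solve and kept weighted;
* *knn* A_knn — cosine k-nearest neighbors of the rows of X (default
  k = 10), symmetrized by union, ties broken toward the lower drug index.

Unit self-loops are added before degree normalization so that isolated
drugs (cold-start folds) are well defined.  In the attention channel a
view contributes its *support* (positive-weight entries plus self-loops)
as the neighborhood mask; edge magnitudes enter only the GCN-style
propagation mode, since softmax attention re-derives its own weights.

**Cross-fusion encoder.** A shared autoencoder learns feature embeddings
H^(l) = relu(W_e^(l) H^(l−1) + b_e^(l)) with H^(0) = X and a mirrored
decoder (linear last layer) producing X̂.  Per view, a stack of
graph-attention layers learns topology embeddings; before each layer the
*convey* step Z̃ = (1−ε) Z + ε H^(l−1) injects the same-depth autoencoder
embedding into the graph stream (ε = 0.5 by default — equal fusion, the
strongest setting in the reference experiments).  Node-level attention is
single-head GAT: e_ij = LeakyReLU(aᵀ[W h_i ∥ W h_j]) (slope 0.2),
α_ij = softmax over i's neighborhood, h_i' = relu(Σ_j α_ij W h_j).

**Dual-level attention.**  Per view, a two-candidate attention pools the
final graph embedding with the final encoder embedding (per-drug weights
from qᵀ tanh(w z + b), softmaxed).  A view-level attention with its own
parameters does the same across the three view embeddings, giving per-drug
weights (ε_a, ε_d, ε_k) summing to 1 and the unified embedding
Z = ε_a Z_adj + ε_d Z_diff + ε_k Z_knn.

**Pair head.**  Two drug embeddings combine by averaging (default;
hadamard, L1 and concatenation are available), pass one hidden ReLU layer
(width 128) and an affine softmax over the C event types.  The hidden layer
is load-bearing: with the averaging combiner, a purely affine head scores
pairs *additively* in the two drug embeddings, and an additive scorer
provably cannot represent an arbitrary map from unordered group pairs to
labels.  On the synthetic fixture the additive ceiling is ≈0.58 accuracy
versus a Bayes level of 0.95; one hidden layer removes the ceiling.
Setting `head_hidden=None` restores the affine head.

**Objective.**  L = L_ce + λ L_re with λ = 1: multiclass cross-entropy
(negative log-likelihood, probabilities clamped at 1e−12) over training
pairs, plus the reconstruction term Σ_i ‖X_i − X̂_i‖₂.  Optimization is
full-batch Adam (learning rate 0.003), at most 1000 epochs, early-stopped
after 20 epochs without improvement of the validation cross-entropy on a
stratified 10% carve-out of the training pairs; the best-validation
checkpoint is restored.  Early stopping is armed only from epoch 150
(`min_epochs`): the full-batch optimizer sometimes crosses a flat plateau
before its main descent, and a bare patience of 20 can freeze a run there
at chance level; the best checkpoint is still tracked from epoch 1.  Parameters are Glorot-uniform initialized —
fan-in-only scaling starts markedly slower on the deep fused stack and
occasionally stalls under patience-20 stopping.  All randomness flows from
one root seed; runs are bit-reproducible.

## Evaluation

Six metrics: accuracy; AUPR and AUC computed micro (one-vs-rest on the
flattened pair×class arrays); precision, recall and F1 macro-averaged over
all C classes, counting classes absent from a fold as 0 — conservative
under long-tailed event distributions.

Three split regimes: Task A partitions *pairs* (both drugs seen in
training); Tasks B and C partition *drugs*, testing pairs with exactly one
(B) or both (C) drugs held out.  In B/C the adjacency and diffusion views
are rebuilt from training pairs only, so held-out drugs are isolated there
and reachable only through the KNN view — the mechanism that makes
cold-start prediction possible.  Pairs joining two held-out drugs are
excluded from Task B's train and test sets.  Each fold retrains from
scratch.

## Ablation variants

`wo_ae` (no autoencoder: pure multiview GAT), `wo_gat` (classify from the
encoder output), `wo_convey` (independent channels, fused only at the
end), `wo_node_att` (GCN propagation D̃^{-1/2} Ã D̃^{-1/2} Z W instead of
attention), `wo_layer_att` (uniform 1/3 view averaging).  Each removes
exactly one mechanism; with ε = 0 and channel fusion forced to the graph
side, the full network's forward pass coincides bit-for-bit with `wo_ae`
on tied weights.

## Synthetic data

The generator plants a recoverable mechanism with the structure the model
assumes: drugs fall into G latent groups; each group has a Bernoulli
descriptor profile per category (bit probability 0.8 on-profile, 0.1 off),
individual bits flipped with probability 0.05; the event type of a pair is
a deterministic function of the unordered group pair (every label used),
flipped to a random other label with probability 0.05.  The default
fixture has 120 drugs, G = 8, C = 8, 40 descriptors per category and 720
pairs; Bayes accuracy is 0.95 and the majority-class chance level ≈0.20.

What the generator does *not* emulate: real descriptor correlation
structure (fingerprint bits are not independent), the extreme 65-class
imbalance of curated event data, or any chemistry.  Passing the fixture
shows the pipeline recovers planted feature-driven structure through the
full architecture; it does not certify performance on curated data.

## Numerical choices and problem sizes

* Attention masking uses an additive −1e30 off-support constant; masked
  entries underflow to exactly 0 after softmax.
* The reconstruction norm's gradient is guarded at 0 (value exact).
* Dense PPR is solved exactly (`scipy.linalg.solve`); a per-row `top_t`
  sparsification is available for graphs beyond desk scale.
* KNN ties (common for binary profiles) break by ascending drug index,
  making every view construction deterministic.
* Test and acceptance runs use hidden widths (128, 64, 32) — three fusion
  layers, matching the depth found best in the reference experiments — and
  a 400-epoch cap (250 for the ten-seed attention experiment), sizes at
  which a fixture training run takes seconds on one CPU.  For
  DDIMDL-scale data (572 drugs, 65 classes) widths of (512, 256, 65) with
  the 1000-epoch cap are the natural setting.

## Known limitations

* Single-head attention only; no relational (event-type-aware) message
  passing; knowledge-graph entities are out of scope.
* The network is dense-matrix throughout: fine to a few thousand drugs,
  not beyond.
* The numpy autodiff core is single-threaded full-batch; no minibatching
  (graph attention wants all nodes per step at this scale anyway).
* With `pair_method="concatenation"` predictions are order-dependent for
  a pair; the canonical (min, max) pair order makes results reproducible
  but the other three combiners are the symmetric choices.
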