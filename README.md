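# mvddi — multiview dual-attention prediction of drug–drug interaction events

Co-administering two drugs can trigger one of dozens of distinct reaction
events (metabolism decreased, serum concentration increased, QTc
prolongation, …).  `mvddi` predicts *which* event a drug pair will produce,
as a C-way classification over drug pairs, by fusing two sources of
information that are individually insufficient:

* **drug attributes** — binary descriptor profiles per category
  (chemical substructure, target, enzyme), turned into Jaccard similarity
  vectors and concatenated into a unified feature matrix X;
* **network topology** — three relational *views* of the drug set: the
  interaction adjacency A_adj, its Personalized PageRank diffusion
  A_diff = α(I − (1−α)D̃^{-1/2}ÃD̃^{-1/2})^{-1}, and a cosine k-nearest-
  neighbor graph A_knn built from X.

A shared autoencoder encodes X while a graph-attention channel per view
encodes topology; at every depth a *convey* step Z̃ = (1−ε)Z + εH mixes
the two streams.  Node-level attention weighs a drug's neighbors
(α_ij = softmax LeakyReLU(aᵀ[Wh_i ∥ Wh_j])) and view-level attention
weighs the three views per drug, giving a unified embedding
Z = ε_a Z_adj + ε_d Z_diff + ε_k Z_knn.  Pair vectors (average of the two
drug embeddings by default) feed a softmax head; training minimizes
cross-entropy plus a reconstruction penalty Σ_i‖X_i − X̂_i‖₂ with Adam.
Because the KNN view depends only on features, the model can score pairs
involving drugs with *no* known interactions (cold start).

The package is written for computational pharmacology researchers who
want a transparent, dependency-light reference implementation: the whole
network runs on a small numpy reverse-mode autodiff core — no GPU, no
deep-learning framework — and every construction (PPR, KNN ties,
initialization) is deterministic given a seed.

## Worked example

Simulate a dataset with planted group structure, train with five-fold
cross-validation, and inspect the attention:

```bash
mvddi simulate --seed 7 --out data/
mvddi train --data data/ --task A --folds 5 --seed 1 --max-epochs 400 --out run_a/
mvddi train --data data/ --task B --folds 5 --seed 1 --max-epochs 400 --out run_b/
mvddi train --data data/ --task C --folds 5 --seed 1 --max-epochs 400 --out run_c/
mvddi export-attention --data data/ --max-epochs 250 --out att/
```

which prints, for the default fixture (120 drugs, 8 event types, 5% label
noise — Bayes accuracy 0.95, majority-class baseline 0.20):

```
wrote 5 data files to data
task A: mean acc 0.939, macro F1 0.938 over 5 folds
task B: mean acc 0.845, macro F1 0.835 over 5 folds
task C: mean acc 0.841, macro F1 0.735 over 5 folds
wrote attention tables to att
```

Task A (both drugs of each test pair seen during training) nearly reaches
the Bayes ceiling; Tasks B and C (one or both drugs completely held out)
drop but stay far above the 0.20 baseline, because the feature-driven KNN
view still connects the new drugs.  Fold-level variance is real: test sets
are small, and individual cold-start folds range from ~0.6 to ~0.95
accuracy depending on which drugs are held out.  `run_a/metrics_mean.tsv` holds all six metrics
(accuracy, micro AUPR/AUC, macro F1/precision/recall);
`att/view_attention.csv` has the per-drug view weights
(`eps_adj`, `eps_diff`, `eps_knn`, each row summing to 1).

The same pipeline is available as a library, shaped like a scikit-learn
estimator:

```python
from mvddi import DDIEventClassifier, default_fixture, unified_features_from_tables

tables, dataset, truth = default_fixture(seed=7)
X = unified_features_from_tables(tables)          # (120, 360)
clf = DDIEventClassifier(drug_features=X.values, num_classes=8,
                         max_epochs=400, random_state=0)
clf.fit(dataset.pair_array(), dataset.label_array())
proba = clf.predict_proba([[0, 5]])               # (1, 8), sums to 1
print(clf.view_weights_.mean(axis=0))             # mean (eps_adj, eps_diff, eps_knn)
```

Real descriptor tables load through `mvddi.data_io.read_feature_table`
(CSV/TSV, first column `drug_id`, binary descriptor columns) and
`read_ddi_edges` (`drug1,drug2,event` with 1-based event labels).

## Layout

| module | contents |
| --- | --- |
| `mvddi.data_io` | feature-table / edge-list / metrics formats, validation |
| `mvddi.features` | Jaccard similarity matrices, unified feature matrix |
| `mvddi.views` | adjacency, PPR diffusion, cosine KNN view graphs |
| `mvddi.autodiff` | minimal reverse-mode autodiff + Adam on numpy |
| `mvddi.model` | the network: AE + per-view GAT, convey, dual attention, losses |
| `mvddi.estimator` | `DDIEventClassifier` (sklearn-style fit/predict) |
| `mvddi.train_eval` | Task A/B/C splits, six-metric report, ablations, exports |
| `mvddi.synthetic` | group-structured synthetic data generator |
| `mvddi.cli` | `mvddi` command-line interface |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
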