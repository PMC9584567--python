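"""Cross-validation splits, training runners, metrics, ablations, exports.

Three evaluation regimes cover increasingly hard generalization:

* **Task A** — pair-level five-fold CV: both drugs of a test pair were seen
  in training (with other partners).
* **Task B** — drug-level CV: each test pair joins one held-out drug with
  one training drug.
* **Task C** — drug-level CV: both drugs of every test pair are held out.

For Tasks B and C the interaction views (adjacency, diffusion) are built
from training-drug edges only, so held-out drugs are isolated there and
reachable only through the feature-similarity KNN view — predictions for
them are genuine cold starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import (average_precision_score, f1_score,
                             precision_score, recall_score, roc_auc_score)

from .data_io import DDIDataset, MetricsReport, ValidationError, METRIC_NAMES
from .estimator import ABLATION_VARIANTS, DDIEventClassifier
from .features import unified_features_from_tables
from .model import one_hot
from .views import build_adjacency, build_views

TASKS = ("A", "B", "C")
VIEW_ORDER = ("adjacency", "diffusion", "knn")


@dataclass
class SplitPlan:
    """Fold assignments for one task.

    Task A assigns each labeled pair to a fold; Tasks B and C assign each
    drug to a fold and derive the pair sets from the drug split.
    """

    task: str
    n_folds: int
    seed: int
    pair_folds: np.ndarray | None    # (L,) fold per pair (Task A)
    drug_folds: np.ndarray | None    # (N,) fold per drug (Tasks B/C)
    dataset: DDIDataset

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train pair indices, test pair indices) for one fold.

        In Task B, pairs with *both* drugs held out belong to neither set
        (they are Task C material); in both B and C the training set keeps
        only pairs entirely inside the training drugs.
        """
        pairs = self.dataset.pair_array()
        if self.task == "A":
            test = np.flatnonzero(self.pair_folds == fold)
            train = np.flatnonzero(self.pair_folds != fold)
            return train, test
        held = self.drug_folds[pairs[:, 0]] == fold, self.drug_folds[pairs[:, 1]] == fold
        n_held = held[0].astype(int) + held[1].astype(int)
        train = np.flatnonzero(n_held == 0)
        test = np.flatnonzero(n_held == (1 if self.task == "B" else 2))
        return train, test


def make_splits(dataset: DDIDataset, task: str, n_folds: int = 5,
                seed: int = 0) -> SplitPlan:
    """Random uniform partition of pairs (Task A) or drugs (Tasks B/C)."""
    if task not in TASKS:
        raise ValidationError(f"unknown task {task!r}")
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    if task == "A":
        n_pairs = len(dataset.pairs)
        if n_pairs < n_folds:
            raise ValidationError("fewer pairs than folds")
        folds = np.repeat(np.arange(n_folds), -(-n_pairs // n_folds))[:n_pairs]
        return SplitPlan(task, n_folds, seed, rng.permutation(folds), None, dataset)
    n = dataset.n_drugs
    if n < n_folds:
        raise ValidationError("fewer drugs than folds")
    folds = np.repeat(np.arange(n_folds), -(-n // n_folds))[:n]
    return SplitPlan(task, n_folds, seed, None, rng.permutation(folds), dataset)


def evaluate(probabilities: np.ndarray, true_labels: np.ndarray,
             num_classes: int) -> MetricsReport:
    """The six-metric report: ACC, micro AUPR/AUC, macro F1/Precision/Recall.

    Micro AUPR and AUC are computed one-vs-rest on the flattened
    (pair x class) score and indicator arrays.  Macro scores average over
    all C classes, counting classes absent from the test fold as 0
    (conservative under the long-tailed event distribution).
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    true_labels = np.asarray(true_labels, dtype=np.intp)
    if probabilities.shape[0] == 0:
        raise ValidationError("empty test set")
    if probabilities.shape != (true_labels.size, num_classes):
        raise ValidationError("probabilities shape does not match labels/C")
    labels = np.arange(1, num_classes + 1)
    pred = labels[np.argmax(probabilities, axis=1)]
    y_bin = one_hot(true_labels, num_classes)
    return MetricsReport(
        acc=float(np.mean(pred == true_labels)),
        aupr_micro=float(average_precision_score(y_bin.ravel(), probabilities.ravel())),
        auc_micro=float(roc_auc_score(y_bin.ravel(), probabilities.ravel())),
        f1_macro=float(f1_score(true_labels, pred, labels=labels,
                                average="macro", zero_division=0)),
        pre_macro=float(precision_score(true_labels, pred, labels=labels,
                                        average="macro", zero_division=0)),
        recall_macro=float(recall_score(true_labels, pred, labels=labels,
                                        average="macro", zero_division=0)),
    )


@dataclass
class FoldResult:
    fold: int
    report: MetricsReport
    estimator: DDIEventClassifier
    n_train: int
    n_test: int


def train_fold(dataset: DDIDataset, features: np.ndarray, plan: SplitPlan,
               fold: int, **estimator_kwargs) -> FoldResult:
    """Fit on one fold's training pairs and evaluate on its test pairs.

    The estimator builds adjacency/diffusion from the training pairs it is
    given, so drug-level leakage into those views is impossible by
    construction; the assertion below re-checks it for Tasks B/C.
    """
    pairs = dataset.pair_array()
    labels = dataset.label_array()
    train_idx, test_idx = plan.fold_indices(fold)
    if train_idx.size == 0 or test_idx.size == 0:
        raise ValidationError(f"fold {fold} has an empty train or test set")
    if plan.task in ("B", "C"):
        train_drugs = np.unique(pairs[train_idx])
        held = np.flatnonzero(plan.drug_folds == fold)
        assert not np.intersect1d(train_drugs, held).size, "split leakage"
    est = DDIEventClassifier(
        drug_features=features, num_classes=dataset.num_event_types,
        **estimator_kwargs)
    est.fit(pairs[train_idx], labels[train_idx])
    report = evaluate(est.predict_proba(pairs[test_idx]), labels[test_idx],
                      dataset.num_event_types)
    return FoldResult(fold, report, est, train_idx.size, test_idx.size)


def cross_validate(dataset: DDIDataset, features: np.ndarray, task: str = "A",
                   n_folds: int = 5, seed: int = 0, **estimator_kwargs
                   ) -> tuple[list[FoldResult], MetricsReport]:
    """Run every fold of a task; the summary averages the six metrics."""
    plan = make_splits(dataset, task, n_folds=n_folds, seed=seed)
    results = []
    for fold in range(n_folds):
        kwargs = dict(estimator_kwargs)
        kwargs.setdefault("random_state", seed + fold)
        results.append(train_fold(dataset, features, plan, fold, **kwargs))
    mean = MetricsReport(**{
        name: float(np.mean([getattr(r.report, name) for r in results]))
        for name in METRIC_NAMES})
    return results, mean


def cross_validate_tables(tables, dataset: DDIDataset, **kwargs):
    """Convenience: raw feature tables -> unified X -> cross_validate."""
    x = unified_features_from_tables(tables)
    return cross_validate(dataset, x.values, **kwargs)


def run_ablation(variant: str, dataset: DDIDataset, features: np.ndarray,
                 task: str = "A", n_folds: int = 5, seed: int = 0,
                 **estimator_kwargs) -> MetricsReport:
    """Cross-validated metrics for one ablation variant of the network."""
    if variant not in ABLATION_VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}; "
                              f"choose from {sorted(ABLATION_VARIANTS)}")
    _, mean = cross_validate(dataset, features, task=task, n_folds=n_folds,
                             seed=seed, variant=variant, **estimator_kwargs)
    return mean


def knn_signal_tracking(dataset: DDIDataset, features: np.ndarray,
                        n_seeds: int = 10, seed: int = 0,
                        **estimator_kwargs) -> list[dict]:
    """Does view-level attention favor the KNN view when topology is noise?

    The adjacency view is rewired to a random graph of equal density (its
    diffusion follows suit), while the feature-derived KNN view keeps the
    real signal.  One model is trained per seed; each run records the mean
    view-level weights and whether the KNN view received the largest.
    """
    from .views import build_diffusion, build_knn, rewire_random

    pairs = dataset.pair_array()
    labels = dataset.label_array()
    adj = build_adjacency(dataset)
    results = []
    for s in range(n_seeds):
        run_seed = (seed + s) % (2**31)
        rewired = rewire_random(adj, seed=run_seed)
        est = DDIEventClassifier(drug_features=features,
                                 num_classes=dataset.num_event_types,
                                 random_state=run_seed, **estimator_kwargs)
        views = {
            "adjacency": rewired,
            "diffusion": build_diffusion(rewired, alpha=est.ppr_alpha),
            "knn": build_knn(features, k=est.knn_k),
        }
        est.fit(pairs, labels, views=views)
        mean_w = est.view_weights_.mean(axis=0)
        results.append({"seed": run_seed,
                        "mean_weights": dict(zip(VIEW_ORDER, mean_w)),
                        "knn_largest": bool(np.argmax(mean_w) == 2)})
    return results


def export_attention(estimator: DDIEventClassifier, drug_ids: list[str],
                     view_path, node_path=None, node_view: str = "knn") -> None:
    """Write the view-level weights and one view's final-layer node attention.

    View-level: CSV ``drug_id,eps_adj,eps_diff,eps_knn`` (rows sum to 1).
    Node-level: square CSV of the last attention layer of ``node_view``.
    """
    estimator._check_fitted()
    if estimator.view_weights_ is None:
        raise ValidationError("this variant has no view-level attention")
    vw = estimator.view_weights_
    pd.DataFrame({"drug_id": drug_ids, "eps_adj": vw[:, 0],
                  "eps_diff": vw[:, 1], "eps_knn": vw[:, 2]}).to_csv(
        view_path, index=False)
    if node_path is not None:
        alphas = estimator.node_attention_.get(node_view, [])
        if not alphas:
            raise ValidationError(f"no node-level attention for view {node_view!r}")
        pd.DataFrame(alphas[-1], index=drug_ids, columns=drug_ids).to_csv(node_path)


def write_history(history: list[dict], path) -> None:
    pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss",
                                   "val_f1_macro"]).to_csv(path, index=False)


def load_config(path) -> dict:
    """Flat key/value (YAML) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a flat key/value mapping")
    return cfg
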