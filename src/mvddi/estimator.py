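"""Scikit-learn style estimator for multitype interaction event prediction.

:class:`DDIEventClassifier` follows the sklearn estimator contract
(`get_params`/`set_params`, ``fit``/``predict``/``predict_proba``, fitted
attributes with trailing underscores), so it composes with sklearn model
selection.  One departure from vanilla tabular estimators is forced by the
problem: a sample is a *pair of drugs*, so ``X`` passed to ``fit`` is an
``(n_pairs, 2)`` integer array of drug indices, and the per-drug unified
feature matrix rides along as the ``drug_features`` parameter.  During
``fit`` the interaction views (adjacency and its diffusion) are built from
the training pairs only, while the KNN view covers every drug through its
features — which is exactly what makes cold-start prediction possible.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split

from .autodiff import Adam, Tensor
from .data_io import ValidationError
from .model import ModelConfig, MultiviewDDINetwork, cross_entropy_loss, one_hot
from .views import build_views

ABLATION_VARIANTS = {
    "full": {},
    "wo_ae": {"use_ae": False, "fusion_eps": 0.0, "channel_fuse": "gat_only"},
    "wo_gat": {"use_gat": False},
    "wo_convey": {"convey": False},
    "wo_node_att": {"node_attention": False},
    "wo_layer_att": {"view_attention": False},
}


class DDIEventClassifier(ClassifierMixin, BaseEstimator):
    """Multiview dual-attention classifier of drug-pair event types.

    Parameters
    ----------
    drug_features : ndarray of shape (n_drugs, n_features)
        Unified per-drug feature matrix (concatenated Jaccard similarity
        profiles; see :mod:`mvddi.features`).
    hidden_widths : tuple of int
        Per-layer embedding sizes shared by the autoencoder and the graph
        channels; the last entry is the pair-embedding dimension.
    fusion_eps : float
        Convey mixing coefficient between the graph stream and the
        autoencoder stream at each layer (0.5 by default).
    pair_method : str
        How two drug embeddings combine into a pair vector: ``average``
        (default, the strongest in the reference experiments),
        ``hadamard``, ``l1`` or ``concatenation``.
    knn_k, ppr_alpha : int, float
        Neighbor count of the KNN view and restart probability of the
        Personalized PageRank diffusion view.
    learning_rate, max_epochs, patience, min_epochs : float, int, int, int
        Adam step size (0.003), epoch cap (1000), early-stopping patience
        in epochs without validation improvement (20), and the earliest
        epoch at which early stopping may trigger (150) — the full-batch
        optimizer sometimes plateaus before its main descent, and the
        best-validation checkpoint is tracked from epoch 1 regardless.
    validation_fraction : float
        Share of training pairs carved out (stratified when possible) to
        monitor early stopping.
    lambda_re : float
        Weight of the reconstruction term in the joint objective.
    variant : str
        ``full`` or one of the ablations ``wo_ae``, ``wo_gat``,
        ``wo_convey``, ``wo_node_att``, ``wo_layer_att``.
    num_classes : int or None
        Number of event types C; inferred as ``max(y)`` when None.
    random_state : int
        Root seed for initialization and the validation split.
    """

    def __init__(self, drug_features=None, *, hidden_widths=(128, 64, 32),
                 head_hidden=128, fusion_eps=0.5, pair_method="average", knn_k=10,
                 ppr_alpha=0.15, diffusion_top_t=None, learning_rate=0.003,
                 max_epochs=1000, patience=20, min_epochs=150,
                 validation_fraction=0.1,
                 lambda_re=1.0, variant="full", num_classes=None,
                 random_state=0, verbose=False):
        self.drug_features = drug_features
        self.hidden_widths = hidden_widths
        self.head_hidden = head_hidden
        self.fusion_eps = fusion_eps
        self.pair_method = pair_method
        self.knn_k = knn_k
        self.ppr_alpha = ppr_alpha
        self.diffusion_top_t = diffusion_top_t
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_epochs = min_epochs
        self.validation_fraction = validation_fraction
        self.lambda_re = lambda_re
        self.variant = variant
        self.num_classes = num_classes
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers --------------------------------------------------------------
    def _validate_pairs(self, X, n_drugs: int) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValidationError("X must be an (n_pairs, 2) array of drug indices")
        X = X.astype(np.intp)
        if X.size and (X.min() < 0 or X.max() >= n_drugs):
            raise ValidationError("pair index outside the drug feature matrix")
        return X

    def _model_config(self, input_dim: int, n_classes: int) -> ModelConfig:
        if self.variant not in ABLATION_VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}")
        overrides = ABLATION_VARIANTS[self.variant]
        base = dict(
            input_dim=input_dim, num_classes=n_classes,
            hidden_widths=tuple(self.hidden_widths),
            head_hidden=self.head_hidden,
            fusion_eps=self.fusion_eps, pair_method=self.pair_method,
            lambda_re=self.lambda_re,
        )
        base.update(overrides)
        return ModelConfig(**base)

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y, views=None):
        """Train on labeled pairs; ``views`` may inject prebuilt view graphs."""
        if self.drug_features is None:
            raise ValidationError("drug_features must be set before fit")
        feats = np.asarray(self.drug_features, dtype=np.float64)
        n_drugs = feats.shape[0]
        X = self._validate_pairs(X, n_drugs)
        y = np.asarray(y, dtype=np.intp)
        if y.shape[0] != X.shape[0]:
            raise ValidationError("X and y disagree on the number of pairs")
        if X.shape[0] == 0:
            raise ValidationError("no training pairs")
        n_classes = int(self.num_classes) if self.num_classes else int(y.max())
        self.classes_ = np.arange(1, n_classes + 1)

        if views is None:
            pair_subset = [(int(i), int(j), 1) for i, j in X]
            views = build_views_from_features(
                feats, pair_subset, knn_k=self.knn_k, ppr_alpha=self.ppr_alpha,
                diffusion_top_t=self.diffusion_top_t)
        self.views_ = views

        # validation carve-out for early stopping (stratified when possible)
        rng_seed = int(self.random_state) % (2**31)
        if self.validation_fraction and X.shape[0] >= 10:
            counts = np.bincount(y, minlength=n_classes + 1)
            strat = y if counts[counts > 0].min() >= 2 else None
            tr_idx, va_idx = train_test_split(
                np.arange(X.shape[0]), test_size=self.validation_fraction,
                random_state=rng_seed, stratify=strat)
        else:
            tr_idx, va_idx = np.arange(X.shape[0]), np.array([], dtype=np.intp)

        cfg = self._model_config(feats.shape[1], n_classes)
        net = MultiviewDDINetwork(cfg, np.random.default_rng(rng_seed))
        opt = Adam(net.parameters(), lr=self.learning_rate)
        x_t = Tensor(feats)
        y_val_onehot = one_hot(y[va_idx], n_classes) if va_idx.size else None

        best_state, best_monitor, bad = None, np.inf, 0
        history: list[dict] = []
        for epoch in range(1, int(self.max_epochs) + 1):
            opt.zero_grad()
            loss, fwd = net.loss(x_t, views, X[tr_idx], y[tr_idx])
            train_loss = float(loss.data) / max(len(tr_idx), 1)
            if not np.isfinite(train_loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={train_loss}")
            loss.backward()
            opt.step()

            if va_idx.size:
                fwd_eval = net.forward(x_t, views)
                probs = net.predict_pairs(fwd_eval["embedding"], X[va_idx])
                val_loss = float(
                    cross_entropy_loss(probs, y_val_onehot).data) / va_idx.size
                val_pred = np.argmax(probs.data, axis=1) + 1
                val_f1 = f1_score(y[va_idx], val_pred, average="macro",
                                  labels=self.classes_, zero_division=0)
                monitor = val_loss
            else:
                val_loss, val_f1 = np.nan, np.nan
                monitor = train_loss
            history.append({"epoch": epoch, "train_loss": train_loss,
                            "val_loss": val_loss, "val_f1_macro": val_f1})
            if self.verbose:
                print(f"epoch {epoch}: train {train_loss:.4f} val {val_loss:.4f}")

            if monitor < best_monitor - 1e-9:
                best_monitor, bad = monitor, 0
                best_state = net.state_dict()
            else:
                bad += 1
            # the floor keeps patience from firing on the early plateau the
            # full-batch optimizer sometimes crosses before its main descent
            if bad >= self.patience and (self.patience == 0
                                         or epoch >= self.min_epochs):
                break

        if best_state is not None:
            net.load_state_dict(best_state)
        fwd = net.forward(x_t, views)
        self.network_ = net
        self.history_ = history
        self.n_epochs_ = len(history)
        self.embedding_ = fwd["embedding"].data.copy()
        vw = fwd["view_weights"]
        self.view_weights_ = None if vw is None else vw.data.copy()
        self.node_attention_ = {
            v: [a.data.copy() for a in alphas]
            for v, alphas in fwd["node_attention"].items()}
        self.n_features_in_ = 2
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pair probability distribution over the C event types."""
        self._check_fitted()
        X = self._validate_pairs(X, self.embedding_.shape[0])
        probs = self.network_.predict_pairs(Tensor(self.embedding_), X)
        return probs.data

    def predict(self, X) -> np.ndarray:
        """Most probable event type (1-based) per pair."""
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise ValidationError("estimator is not fitted; call fit first")


def build_views_from_features(feats: np.ndarray, pair_subset, *, knn_k=10,
                              ppr_alpha=0.15, diffusion_top_t=None):
    """Views from a raw feature matrix and an (i, j, y) pair list."""
    from .data_io import DDIDataset

    n = feats.shape[0]
    dataset = DDIDataset(drug_ids=[str(i) for i in range(n)],
                         pairs=list(pair_subset), num_event_types=max(
                             (y for *_, y in pair_subset), default=1))
    return build_views(dataset, feats, knn_k=knn_k, ppr_alpha=ppr_alpha,
                       diffusion_top_t=diffusion_top_t)
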