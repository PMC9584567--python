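"""Multiview dual-level-attention network for interaction event prediction.

Architecture, per forward pass over all N drugs at once:

1. A shared **autoencoder channel** encodes the unified feature matrix X
   through ReLU affine layers ``H^(l) = relu(W_e^(l) H^(l-1) + b_e^(l))``
   (H^(0) = X) and decodes back to a reconstruction X̂ through a mirrored
   decoder (linear output layer).
2. A **graph channel per view** (adjacency / diffusion / knn) runs L
   graph-attention layers.  Before each layer the *convey* operation mixes
   the autoencoder embedding into the graph stream,
   ``Z~ = (1 − eps) Z + eps H``, so feature and topology information cross
   at every depth.  Each layer either aggregates with learned node-level
   attention (GAT, default) or with the fixed symmetric-normalized
   propagation D̃^{-1/2} Ã D̃^{-1/2} (GCN mode, used by the no-node-attention
   ablation).
3. Per view, a small **channel-fusion attention** combines the final graph
   embedding with the final encoder embedding; a **view-level attention**
   (shared vector q over tanh-transformed embeddings, softmax across the
   three views per drug) then produces the unified embedding
   ``Z = eps_a Z_adj + eps_d Z_diff + eps_k Z_knn``.
4. Drug-pair vectors (average / hadamard / l1 / concatenation of the two
   drug embeddings) go through an affine softmax head over the C event
   types.

The training objective is cross-entropy over labeled pairs plus a weighted
reconstruction term  ``sum_i ‖X_i − X̂_i‖₂``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat, softmax
from .data_io import ValidationError
from .views import ViewGraph, VIEW_NAMES

PAIR_METHODS = ("average", "hadamard", "l1", "concatenation")
_NEG_INF = -1e30


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    ``hidden_widths`` are the per-layer embedding sizes shared by the
    encoder and every graph channel; the last width is the embedding
    dimension d used for pair vectors.  ``fusion_eps`` is the convey mixing
    coefficient (0.5 performs best in the reference experiments).  The
    boolean switches implement the ablation variants: each removes exactly
    one mechanism while keeping the rest of the pipeline intact.
    """

    input_dim: int
    num_classes: int
    hidden_widths: tuple[int, ...] = (128, 64, 32)
    fusion_eps: float = 0.5
    pair_method: str = "average"
    lambda_re: float = 1.0
    leaky_slope: float = 0.2
    head_hidden: int | None = 128  # hidden width of the pair head; None = affine
    use_ae: bool = True          # False: pure multi-view GAT (w/o AE)
    use_gat: bool = True         # False: classify from encoder output (w/o GAT)
    convey: bool = True          # False: independent channels (w/o Convey)
    node_attention: bool = True  # False: GCN propagation (w/o NodeAtt)
    view_attention: bool = True  # False: unweighted view average (w/o LayerAtt)
    channel_fuse: str = "attention"  # "attention" | "gat_only"

    def __post_init__(self):
        if self.pair_method not in PAIR_METHODS:
            raise ValidationError(f"unknown pair method {self.pair_method!r}")
        if not (0.0 <= self.fusion_eps <= 1.0):
            raise ValidationError("fusion_eps must lie in [0, 1]")
        if self.channel_fuse not in ("attention", "gat_only"):
            raise ValidationError(f"unknown channel_fuse {self.channel_fuse!r}")
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)

    @property
    def n_layers(self) -> int:
        return len(self.hidden_widths)

    @property
    def embedding_dim(self) -> int:
        return self.hidden_widths[-1]


# ---------------------------------------------------------------------------
# elementary operations (each usable standalone)
# ---------------------------------------------------------------------------

def convey(z_prev: Tensor, h_prev: Tensor, eps: float) -> Tensor:
    """Convex mix Z~ = (1 − eps) Z + eps H injecting AE features into a view."""
    if z_prev.shape != h_prev.shape:
        raise ValidationError(f"shape mismatch {z_prev.shape} vs {h_prev.shape}")
    if eps == 0.0:
        return z_prev
    if eps == 1.0:
        return h_prev
    return (1.0 - eps) * z_prev + eps * h_prev


def node_attention(h: Tensor, mask: np.ndarray, W: Tensor, a: Tensor,
                   slope: float = 0.2) -> tuple[Tensor, Tensor]:
    """GAT attention: alpha_ij = softmax_j LeakyReLU(aᵀ[Wh_i ∥ Wh_j]).

    ``mask`` is the boolean neighborhood support (self-loops included).
    Returns (alpha, Wh); each alpha row sums to 1 over the neighborhood.
    """
    n = h.shape[0]
    d_out = W.shape[1]
    wh = h @ W
    f_src = wh @ a.take_rows(np.arange(d_out))        # aᵀ first half  -> (N, 1)
    f_dst = wh @ a.take_rows(np.arange(d_out, 2 * d_out))
    e = (f_src.reshape(n, 1) + f_dst.reshape(1, n)).leaky_relu(slope)
    mask = mask.astype(np.float64)
    e_masked = e * Tensor(mask) + Tensor(_NEG_INF * (1.0 - mask))
    alpha = softmax(e_masked, axis=1)
    return alpha, wh


def gat_layer(z_tilde: Tensor, graph_mask: np.ndarray, W: Tensor, a: Tensor,
              slope: float = 0.2, propagation: np.ndarray | None = None
              ) -> tuple[Tensor, Tensor | None]:
    """One graph layer: attention aggregation or fixed normalized propagation.

    Default: h_i = relu(sum_j alpha_ij W h~_j).  With ``propagation`` given
    (a precomputed D̃^{-1/2} Ã D̃^{-1/2}), the attention-free variant
    relu(S Z~ W) is applied instead and no alpha is returned.
    """
    if propagation is not None:
        return (Tensor(propagation) @ z_tilde @ W).relu(), None
    alpha, wh = node_attention(z_tilde, graph_mask, W, a, slope)
    return (alpha @ wh).relu(), alpha


def attention_pool(mats: list[Tensor], w: Tensor, b: Tensor, q: Tensor
                   ) -> tuple[Tensor, Tensor]:
    """Shared-vector attention over a set of equally shaped embeddings.

    Per drug i and candidate y the score is qᵀ tanh(w z_y,i + b); softmax
    across candidates gives per-drug weights summing to 1.  Returns
    (weights (N, len(mats)), fused (N, d)).  Used both for the per-view
    channel fusion (two candidates) and the view-level fusion (three).
    """
    scores = [((m @ w.T + b).tanh() @ q).reshape(-1, 1) for m in mats]
    weights = softmax(concat(scores, axis=1), axis=1)
    fused = fuse_weighted(mats, weights)
    return weights, fused


def fuse_weighted(mats: list[Tensor], weights: Tensor) -> Tensor:
    """Per-drug convex combination sum_y weights[:, y] * Z_y."""
    out = None
    for y, m in enumerate(mats):
        col = Tensor(np.eye(weights.shape[1])[:, [y]])
        w_y = weights @ col  # (N, 1) selects candidate y's weight per drug
        out = w_y * m if out is None else out + w_y * m
    return out


def pair_vector(z_i: Tensor, z_j: Tensor, method: str) -> Tensor:
    """Combine two drug embeddings into a pair representation (Table-style).

    average / hadamard / l1 are symmetric in (i, j) and keep dimension d;
    concatenation doubles it.
    """
    if method == "average":
        return (z_i + z_j) * 0.5
    if method == "hadamard":
        return z_i * z_j
    if method == "l1":
        return (z_i - z_j).abs()
    if method == "concatenation":
        return concat([z_i, z_j], axis=1)
    raise ValidationError(f"unknown pair method {method!r}")


def classify_pairs(pair_vectors: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Affine map to C logits then row softmax: per-pair class distribution."""
    return softmax(pair_vectors @ W + b, axis=1)


def reconstruction_loss(x, x_hat) -> Tensor:
    """Sum over drugs of the Euclidean norm of the reconstruction residual."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    x_hat = x_hat if isinstance(x_hat, Tensor) else Tensor(x_hat)
    if x.shape != x_hat.shape:
        raise ValidationError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    diff = x - x_hat
    return ((diff * diff).sum(axis=1).sqrt()).sum()


def cross_entropy_loss(probs, y_onehot) -> Tensor:
    """Negative log-likelihood −sum_l sum_c Y lnŶ; probabilities clamped ≥ 1e-12."""
    probs = probs if isinstance(probs, Tensor) else Tensor(probs)
    y = np.asarray(y_onehot, dtype=np.float64)
    if probs.shape != y.shape:
        raise ValidationError(f"shape mismatch {probs.shape} vs {y.shape}")
    return -(Tensor(y) * probs.clip_min(1e-12).log()).sum()


def total_loss(lce, lre, lambda_re: float):
    """Joint objective: cross-entropy plus weighted reconstruction."""
    return lce + lambda_re * lre


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """1-based labels -> (L, C) one-hot matrix."""
    labels = np.asarray(labels, dtype=np.intp)
    if labels.size and (labels.min() < 1 or labels.max() > num_classes):
        raise ValidationError("label outside 1..C")
    out = np.zeros((labels.size, num_classes))
    out[np.arange(labels.size), labels - 1] = 1.0
    return out


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------

class MultiviewDDINetwork:
    """Parameter container + forward pass over precomputed view graphs."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.params: dict[str, Tensor] = {}
        cfg = config
        dims = (cfg.input_dim, *cfg.hidden_widths)
        if cfg.use_ae:
            for l in range(cfg.n_layers):
                self._add(f"ae.enc{l}.W", rng, (dims[l], dims[l + 1]))
                self._add(f"ae.enc{l}.b", rng, (dims[l + 1],))
            dec_dims = dims[::-1]
            for l in range(cfg.n_layers):
                self._add(f"ae.dec{l}.W", rng, (dec_dims[l], dec_dims[l + 1]))
                self._add(f"ae.dec{l}.b", rng, (dec_dims[l + 1],))
        if cfg.use_gat:
            for view in VIEW_NAMES:
                for l in range(cfg.n_layers):
                    self._add(f"gat.{view}.l{l}.W", rng, (dims[l], dims[l + 1]))
                    if cfg.node_attention:
                        # column matrix so both halves slice as (d, 1)
                        self._add(f"gat.{view}.l{l}.a", rng, (2 * dims[l + 1], 1))
                if cfg.use_ae and cfg.channel_fuse == "attention":
                    d = cfg.embedding_dim
                    self._add(f"chfuse.{view}.w", rng, (d, d))
                    self._add(f"chfuse.{view}.b", rng, (d,))
                    self._add(f"chfuse.{view}.q", rng, (d, 1))
            if cfg.view_attention:
                d = cfg.embedding_dim
                self._add("viewatt.w", rng, (d, d))
                self._add("viewatt.b", rng, (d,))
                self._add("viewatt.q", rng, (d, 1))
        head_in = cfg.embedding_dim * (2 if cfg.pair_method == "concatenation" else 1)
        if cfg.head_hidden:
            # a nonlinear head lets the class score depend non-additively on
            # the two drug embeddings (an affine head over an averaged pair
            # vector can only express additive pair scores)
            self._add("head.hidden.W", rng, (head_in, cfg.head_hidden))
            self._add("head.hidden.b", rng, (cfg.head_hidden,))
            head_in = cfg.head_hidden
        self._add("head.W", rng, (head_in, cfg.num_classes))
        self._add("head.b", rng, (cfg.num_classes,))

    def _add(self, name: str, rng: np.random.Generator, shape: tuple[int, ...]):
        # Glorot-uniform keeps activation variance stable through the deep
        # stack of fused channels; fan-in-only scaling starts noticeably
        # slower here.  All randomness flows from the caller's generator.
        fan_in = shape[0]
        fan_out = shape[1] if len(shape) > 1 else shape[0]
        bound = np.sqrt(6.0 / max(fan_in + fan_out, 1))
        self.params[name] = Tensor(rng.uniform(-bound, bound, size=shape),
                                   requires_grad=True)

    # -- parameter plumbing ---------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise ValidationError(f"unexpected parameter {k!r}")
            if self.params[k].data.shape != v.shape:
                raise ValidationError(f"shape mismatch for {k!r}")
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    def save(self, path) -> None:
        """Checkpoint: all parameter tensors plus the config as metadata."""
        meta = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "MultiviewDDINetwork":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"]).decode())
            meta["hidden_widths"] = tuple(meta["hidden_widths"])
            net = cls(ModelConfig(**meta), np.random.default_rng(0))
            net.load_state_dict(
                {k: data[k] for k in data.files if k != "__config__"})
        return net

    # -- forward --------------------------------------------------------------
    def _encode(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        cfg = self.config
        h_layers = [x]
        h = x
        for l in range(cfg.n_layers):
            h = (h @ self.params[f"ae.enc{l}.W"] + self.params[f"ae.enc{l}.b"]).relu()
            h_layers.append(h)
        out = h
        for l in range(cfg.n_layers):
            out = out @ self.params[f"ae.dec{l}.W"] + self.params[f"ae.dec{l}.b"]
            if l < cfg.n_layers - 1:
                out = out.relu()
        return h_layers, out

    def forward(self, x, views: dict[str, ViewGraph]) -> dict:
        """Full drug-embedding pass.

        Returns a dict with the unified embedding ``Z``, per-view
        embeddings, view-level weights, node-level attention matrices per
        view per layer, the encoder trajectory and the reconstruction.
        """
        cfg = self.config
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        out: dict = {"node_attention": {v: [] for v in VIEW_NAMES}}

        if cfg.use_ae:
            h_layers, recon = self._encode(x)
            out["ae_layers"], out["reconstruction"] = h_layers, recon
        else:
            h_layers, recon = None, None

        if not cfg.use_gat:
            out["embedding"] = h_layers[-1]
            out["view_weights"] = None
            return out

        propagations = None
        if not cfg.node_attention:
            propagations = {v: self._propagation(g) for v, g in views.items()}

        view_embeddings: list[Tensor] = []
        channel_weights: dict[str, Tensor] = {}
        for view in VIEW_NAMES:
            graph = views[view]
            mask = graph.support()
            z = x
            for l in range(cfg.n_layers):
                if cfg.use_ae and cfg.convey:
                    z = convey(z, h_layers[l], cfg.fusion_eps)
                W = self.params[f"gat.{view}.l{l}.W"]
                if cfg.node_attention:
                    z, alpha = gat_layer(z, mask, W,
                                         self.params[f"gat.{view}.l{l}.a"],
                                         cfg.leaky_slope)
                    out["node_attention"][view].append(alpha)
                else:
                    z, _ = gat_layer(z, mask, W, None,
                                     propagation=propagations[view])
            if cfg.use_ae and cfg.channel_fuse == "attention":
                w2 = self.params[f"chfuse.{view}.w"]
                b2 = self.params[f"chfuse.{view}.b"]
                q2 = self.params[f"chfuse.{view}.q"]
                cw, z = attention_pool([z, h_layers[-1]], w2, b2, q2)
                channel_weights[view] = cw
            view_embeddings.append(z)

        if cfg.view_attention:
            vw, z_unified = attention_pool(
                view_embeddings, self.params["viewatt.w"],
                self.params["viewatt.b"], self.params["viewatt.q"])
        else:
            n = view_embeddings[0].shape[0]
            vw = Tensor(np.full((n, len(view_embeddings)), 1.0 / len(view_embeddings)))
            z_unified = fuse_weighted(view_embeddings, vw)

        out["view_embeddings"] = dict(zip(VIEW_NAMES, view_embeddings))
        out["channel_weights"] = channel_weights
        out["view_weights"] = vw
        out["embedding"] = z_unified
        return out

    @staticmethod
    def _propagation(graph: ViewGraph) -> np.ndarray:
        """Self-loop-augmented symmetric normalization D̃^{-1/2} Ã D̃^{-1/2}."""
        a = graph.weights.copy()
        np.fill_diagonal(a, np.diag(a) + 1.0)
        deg = a.sum(axis=1)
        d_inv_sqrt = 1.0 / np.sqrt(deg)
        return a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]

    def predict_pairs(self, embedding: Tensor, pairs: np.ndarray) -> Tensor:
        """Class distributions for an (L, 2) array of drug-index pairs."""
        pairs = np.asarray(pairs, dtype=np.intp)
        z_i = embedding.take_rows(pairs[:, 0])
        z_j = embedding.take_rows(pairs[:, 1])
        pv = pair_vector(z_i, z_j, self.config.pair_method)
        if self.config.head_hidden:
            pv = (pv @ self.params["head.hidden.W"]
                  + self.params["head.hidden.b"]).relu()
        return classify_pairs(pv, self.params["head.W"], self.params["head.b"])

    def loss(self, x, views: dict[str, ViewGraph], pairs: np.ndarray,
             labels: np.ndarray) -> tuple[Tensor, dict]:
        """Joint objective on a pair batch; also returns the forward dict."""
        fwd = self.forward(x, views)
        probs = self.predict_pairs(fwd["embedding"], pairs)
        fwd["probabilities"] = probs
        lce = cross_entropy_loss(probs, one_hot(labels, self.config.num_classes))
        if self.config.use_ae:
            lre = reconstruction_loss(
                x if isinstance(x, Tensor) else Tensor(x), fwd["reconstruction"])
            lt = total_loss(lce, lre, self.config.lambda_re)
        else:
            lre = Tensor(0.0)
            lt = lce
        fwd["loss_ce"], fwd["loss_re"] = lce, lre
        return lt, fwd
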