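"""Construction of the three relational views over the drug set.

* adjacency — binary graph of observed interactions (any event type);
* diffusion — Personalized PageRank of the adjacency,
  ``alpha * (I − (1 − alpha) * D^{-1/2} A D^{-1/2})^{-1}``, capturing
  multi-hop proximity as dense nonnegative weights;
* knn — cosine-similarity nearest neighbors in unified feature space,
  symmetrized by union, connecting drugs with no interaction edges at all
  (the cold-start mechanism).

Isolated nodes make the inverse square-root degree undefined, so unit
self-loops are added before normalization by default (the renormalization
trick); a ``self_loops=False`` escape hatch exists for graphs already known
to have no isolated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .data_io import DDIDataset, ValidationError
from .features import UnifiedFeatureMatrix

VIEW_NAMES = ("adjacency", "diffusion", "knn")


@dataclass
class ViewGraph:
    """One weighted symmetric graph over the drug set."""

    view: str
    weights: np.ndarray  # (N, N), entries >= 0
    self_loops: bool = False

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def support(self) -> np.ndarray:
        """Boolean neighborhood mask including self-loops (used by attention)."""
        mask = self.weights > 0
        np.fill_diagonal(mask, True)
        return mask


def build_adjacency(dataset: DDIDataset, pair_subset=None) -> ViewGraph:
    """Binary interaction graph: (i,j)=1 iff a labeled pair {i,j} exists.

    ``pair_subset`` restricts the edges to the given (i, j, y) triples —
    cross-validation builds the graph from training pairs only so held-out
    drugs stay isolated.
    """
    n = dataset.n_drugs
    a = np.zeros((n, n))
    for i, j, _y in (dataset.pairs if pair_subset is None else pair_subset):
        a[i, j] = a[j, i] = 1.0
    np.fill_diagonal(a, 0.0)
    return ViewGraph("adjacency", a)


def _sym_normalize(a: np.ndarray) -> np.ndarray:
    """D^{-1/2} A D^{-1/2}; requires every node degree > 0."""
    deg = a.sum(axis=1)
    if np.any(deg <= 0):
        raise ValidationError(
            "isolated node(s) with zero degree; add self-loops before normalizing"
        )
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def build_diffusion(adj: ViewGraph, alpha: float = 0.15,
                    self_loops: bool = True, top_t: int | None = None) -> ViewGraph:
    """Personalized PageRank diffusion of a symmetric adjacency.

    Solves ``alpha * (I − (1 − alpha) S)^{-1}`` exactly with a dense linear
    solve, where ``S`` is the symmetrically normalized (optionally
    self-loop-augmented) adjacency.  ``top_t`` keeps only the ``t`` largest
    weights per row (then re-symmetrizes by max) for large graphs; by
    default the dense matrix is kept as edge weights.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    a = np.asarray(adj.weights, dtype=np.float64).copy()
    if not np.allclose(a, a.T):
        raise ValidationError("diffusion requires a symmetric adjacency")
    if self_loops:
        np.fill_diagonal(a, np.diag(a) + 1.0)
    s = _sym_normalize(a)
    n = s.shape[0]
    system = np.eye(n) - (1.0 - alpha) * s
    try:
        diff = alpha * scipy.linalg.solve(system, np.eye(n), assume_a="sym")
    except scipy.linalg.LinAlgError as err:  # pragma: no cover - guarded
        raise ValidationError(f"PPR system singular: {err}") from err
    diff = np.maximum((diff + diff.T) / 2.0, 0.0)  # kill asymmetric round-off
    if top_t is not None:
        keep = np.zeros_like(diff, dtype=bool)
        order = np.argsort(-diff, axis=1, kind="stable")
        rows = np.arange(n)[:, None]
        keep[rows, order[:, :top_t]] = True
        diff = np.where(keep | keep.T, diff, 0.0)
    return ViewGraph("diffusion", diff, self_loops=self_loops)


def cosine_similarity(u, v) -> float:
    """u·v / (‖u‖‖v‖); defined as 0 when either vector is all zeros."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValidationError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(u @ v / (nu * nv))


def build_knn(x: UnifiedFeatureMatrix | np.ndarray, k: int = 10) -> ViewGraph:
    """K-nearest-neighbor graph by cosine similarity in feature space.

    Each drug links to its ``k`` most similar other drugs; the union of the
    directed choices gives the undirected graph.  Ties on similarity break
    toward the lower drug index, making the construction deterministic.
    Similarities are quantized to 1e-9 before ranking so that exact ties —
    common for binary descriptor profiles — rank identically no matter how
    the floating-point dot products were accumulated.
    """
    values = x.values if isinstance(x, UnifiedFeatureMatrix) else np.asarray(x, float)
    n = values.shape[0]
    if k < 1 or k >= n:
        raise ValidationError(f"need 1 <= k < n_drugs, got k={k}, n={n}")
    norms = np.linalg.norm(values, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = values / safe[:, None]
    sim = np.round(unit @ unit.T, 9)
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    np.fill_diagonal(sim, -np.inf)  # self excluded
    # lexsort: primary key descending similarity, secondary ascending index
    idx = np.arange(n)
    a = np.zeros((n, n))
    for i in range(n):
        order = np.lexsort((idx, -sim[i]))
        nbrs = order[:k]
        a[i, nbrs] = 1.0
    a = np.maximum(a, a.T)  # union symmetrization
    np.fill_diagonal(a, 0.0)
    return ViewGraph("knn", a)


def build_views(dataset: DDIDataset, x: UnifiedFeatureMatrix | np.ndarray,
                pair_subset=None, knn_k: int = 10, ppr_alpha: float = 0.15,
                diffusion_top_t: int | None = None) -> dict[str, ViewGraph]:
    """Build all three views from a pair set and the unified features."""
    adj = build_adjacency(dataset, pair_subset=pair_subset)
    return {
        "adjacency": adj,
        "diffusion": build_diffusion(adj, alpha=ppr_alpha, top_t=diffusion_top_t),
        "knn": build_knn(x, k=knn_k),
    }


def rewire_random(graph: ViewGraph, seed: int = 0) -> ViewGraph:
    """Replace a binary graph's edge set by a uniform random one of equal size.

    Destroys any relationship between the topology and the labels while
    preserving density — used to test whether the view-level attention
    learns to discount an uninformative view.
    """
    n = graph.n_nodes
    n_edges = int(np.triu(graph.weights > 0, k=1).sum())
    rng = np.random.default_rng(seed)
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    chosen = rng.choice(len(all_pairs), size=n_edges, replace=False)
    a = np.zeros((n, n))
    for k in chosen:
        i, j = all_pairs[k]
        a[i, j] = a[j, i] = 1.0
    return ViewGraph(graph.view, a, self_loops=graph.self_loops)


def write_view(graph: ViewGraph, path, drug_ids: list[str] | None = None) -> None:
    ids = drug_ids if drug_ids is not None else list(range(graph.n_nodes))
    pd.DataFrame(graph.weights, index=ids, columns=ids).to_csv(path)


def write_edge_list(graph: ViewGraph, path) -> None:
    i, j = np.nonzero(np.triu(graph.weights, k=1))
    pd.DataFrame({"i": i, "j": j, "w": graph.weights[i, j]}).to_csv(path, index=False)
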