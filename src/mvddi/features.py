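"""Jaccard similarity profiles and the unified drug feature matrix.

Each drug arrives as a binary descriptor vector per category (chemical
substructure, target, enzyme).  Within a category, drug similarity is the
Jaccard index of the two bit sets; stacking all pairwise similarities gives
an N x N similarity matrix per category, and concatenating the per-category
rows gives the unified feature matrix X (N x 3N for three categories) that
feeds both the autoencoder channel and the KNN view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import DrugFeatureTable, ValidationError


@dataclass
class SimilarityMatrix:
    """Symmetric N x N Jaccard similarity matrix for one feature category."""

    category: str
    drug_ids: list[str]
    values: np.ndarray

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)


@dataclass
class UnifiedFeatureMatrix:
    """Row-per-drug concatenation of per-category similarity profiles."""

    drug_ids: list[str]
    values: np.ndarray  # (N, sum of block widths)
    column_blocks: list[tuple[str, int, int]]  # (category, start, stop)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)


def jaccard_similarity(a, b) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b| of two binary vectors.

    Two empty bit sets have an undefined ratio (0/0); we return 0 so an
    uncharacterized drug looks dissimilar to everything.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def build_similarity_matrix(table: DrugFeatureTable) -> SimilarityMatrix:
    """All-pairs Jaccard similarity of a binary descriptor table.

    Vectorized over the whole table: with B the 0/1 matrix, intersections
    are B Bᵀ and unions follow from |a ∪ b| = |a| + |b| − |a ∩ b|.  Rows
    with no set bits get similarity 0 to every other drug and 1 to
    themselves (every diagonal entry is 1).
    """
    b = table.values.astype(np.float64)
    inter = b @ b.T
    sizes = b.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(table.category, list(table.drug_ids), sim)


def build_unified_features(matrices: list[SimilarityMatrix]) -> UnifiedFeatureMatrix:
    """Concatenate per-category similarity profiles column-wise into X."""
    if not matrices:
        raise ValidationError("no similarity matrices given")
    drug_ids = matrices[0].drug_ids
    for m in matrices[1:]:
        if m.drug_ids != drug_ids:
            raise ValidationError(
                f"drug order of {m.category!r} differs from {matrices[0].category!r}"
            )
    blocks: list[tuple[str, int, int]] = []
    offset = 0
    for m in matrices:
        width = m.values.shape[1]
        blocks.append((m.category, offset, offset + width))
        offset += width
    values = np.concatenate([m.values for m in matrices], axis=1)
    return UnifiedFeatureMatrix(list(drug_ids), values, blocks)


def unified_features_from_tables(tables: list[DrugFeatureTable]) -> UnifiedFeatureMatrix:
    """Convenience: tables -> per-category Jaccard matrices -> unified X."""
    return build_unified_features([build_similarity_matrix(t) for t in tables])


def write_similarity_matrix(matrix: SimilarityMatrix, path) -> None:
    pd.DataFrame(matrix.values, index=matrix.drug_ids, columns=matrix.drug_ids).to_csv(path)


def read_similarity_matrix(path, category: str) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return SimilarityMatrix(category, [str(d) for d in df.index], df.to_numpy())
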