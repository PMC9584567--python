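"""Synthetic interaction datasets with planted group structure.

The generator emulates the shape of curated multitype DDI data: per-drug
binary descriptor tables in three categories, and a symmetric labeled pair
set with a long-tailed event distribution.  The planted mechanism is
simple and fully known: drugs belong to latent groups, each group has a
Bernoulli descriptor profile per category, and the event type of a pair is
a deterministic function of the unordered group pair, corrupted by label
noise.  Because the label is a function of the groups, the Bayes accuracy
is exactly ``1 − label_noise``, which makes recovery thresholds analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .data_io import DDIDataset, DrugFeatureTable, ValidationError

CATEGORIES = ("substructure", "target", "enzyme")


@dataclass
class SimConfig:
    """Study conditions of the synthetic fixture.

    Defaults are the package's standard test fixture: 120 drugs in 8
    groups, 8 event types, 40 descriptors per category, on average 12
    labeled pairs per drug, 5% label noise and 5% descriptor bit flips.
    """

    n_drugs: int = 120
    n_groups: int = 8
    descriptors_per_category: tuple[int, int, int] = (40, 40, 40)
    n_classes: int = 8
    pairs_per_drug: float = 12.0
    label_noise: float = 0.05
    feature_flip_noise: float = 0.05
    within_group_bit_p: float = 0.8
    cross_group_bit_p: float = 0.1
    group_weights: tuple[float, ...] | None = None
    seed: int = 7

    def __post_init__(self):
        n_cells = self.n_groups * (self.n_groups + 1) // 2
        if self.n_classes > n_cells:
            raise ValidationError(
                f"C={self.n_classes} event types need at least as many "
                f"group-pair cells; G={self.n_groups} gives only {n_cells}")
        for p in (self.label_noise, self.feature_flip_noise,
                  self.within_group_bit_p, self.cross_group_bit_p):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.group_weights is not None and len(self.group_weights) != self.n_groups:
            raise ValidationError("group_weights length must equal n_groups")


@dataclass
class GroundTruth:
    """Latent state of a simulated dataset."""

    groups: np.ndarray                       # (N,) group index per drug
    pair_label_map: dict[tuple[int, int], int]  # unordered group pair -> label
    clean_labels: np.ndarray                 # labels before noise


def simulate_ddi(config: SimConfig) -> tuple[list[DrugFeatureTable], DDIDataset, GroundTruth]:
    """Draw one dataset: three feature tables, a labeled pair set, the truth."""
    rng = np.random.default_rng(config.seed)
    n, g, c = config.n_drugs, config.n_groups, config.n_classes

    weights = (np.full(g, 1.0 / g) if config.group_weights is None
               else np.asarray(config.group_weights, float) / np.sum(config.group_weights))
    groups = rng.choice(g, size=n, p=weights)
    drug_ids = [f"D{i:04d}" for i in range(n)]

    # per-group Bernoulli descriptor profile per category; per-drug bits
    tables: list[DrugFeatureTable] = []
    for cat, f_cat in zip(CATEGORIES, config.descriptors_per_category):
        profile = np.where(rng.random((g, f_cat)) < 0.5, 1, 0)
        p = np.where(profile[groups] == 1,
                     config.within_group_bit_p, config.cross_group_bit_p)
        bits = (rng.random((n, f_cat)) < p).astype(float)
        flip = rng.random((n, f_cat)) < config.feature_flip_noise
        bits = np.where(flip, 1.0 - bits, bits)
        tables.append(DrugFeatureTable(
            category=cat, drug_ids=list(drug_ids),
            descriptors=[f"{cat[:3]}_{k}" for k in range(f_cat)], values=bits))

    # deterministic unordered-group-pair -> label map covering every label
    cells = list(combinations_with_replacement(range(g), 2))
    perm = rng.permutation(len(cells))
    pair_label_map: dict[tuple[int, int], int] = {}
    for rank, cell_idx in enumerate(perm):
        # first C cells get distinct labels so each label occurs; the rest reuse
        label = rank + 1 if rank < c else int(rng.integers(1, c + 1))
        pair_label_map[cells[cell_idx]] = label

    # sample unordered drug pairs without replacement
    target_pairs = int(round(config.pairs_per_drug * n / 2))
    all_pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    if target_pairs > len(all_pairs):
        raise ValidationError("pairs_per_drug too large for n_drugs")
    chosen = all_pairs[rng.choice(len(all_pairs), size=target_pairs, replace=False)]

    clean = np.empty(target_pairs, dtype=np.intp)
    labels = np.empty(target_pairs, dtype=np.intp)
    for k, (i, j) in enumerate(chosen):
        gi, gj = sorted((groups[i], groups[j]))
        y = pair_label_map[(gi, gj)]
        clean[k] = y
        if config.label_noise and rng.random() < config.label_noise and c > 1:
            others = [cc for cc in range(1, c + 1) if cc != y]
            y = int(others[rng.integers(len(others))])
        labels[k] = y

    dataset = DDIDataset(
        drug_ids=list(drug_ids),
        pairs=[(int(i), int(j), int(y)) for (i, j), y in zip(chosen, labels)],
        num_event_types=c)
    # the dataset canonicalizes pair order; align the clean labels with it
    clean_by_pair = {(int(i), int(j)): int(y) for (i, j), y in zip(chosen, clean)}
    clean_sorted = np.array([clean_by_pair[(i, j)] for i, j, _ in dataset.pairs],
                            dtype=np.intp)
    return tables, dataset, GroundTruth(groups, pair_label_map, clean_sorted)


def chance_level(dataset: DDIDataset) -> float:
    """Accuracy of the majority-class predictor: max class frequency."""
    labels = dataset.label_array()
    if labels.size == 0:
        raise ValidationError("empty dataset")
    return float(np.bincount(labels).max() / labels.size)


def write_ground_truth(truth: GroundTruth, drug_ids: list[str], path) -> None:
    pd.DataFrame({"drug_id": drug_ids, "group": truth.groups}).to_csv(path, index=False)


def default_fixture(seed: int = 7) -> tuple[list[DrugFeatureTable], DDIDataset, GroundTruth]:
    """The standard 120-drug / 8-class fixture used across the test suite."""
    return simulate_ddi(SimConfig(seed=seed))
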