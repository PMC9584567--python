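"""On-disk formats and validated in-memory containers.

Three kinds of artifact travel through the package:

* per-category binary drug descriptor tables (CSV/TSV, first column
  ``drug_id``, remaining columns 0/1 descriptor bits),
* the labeled interaction edge list (``drug1,drug2,event`` with a 1-based
  integer event type),
* flat key/value metric reports.

Drug order is canonical: the row order of the first feature table loaded
fixes the index every matrix in the pipeline shares.  Interaction pairs are
unordered; they are stored canonically as (min index, max index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METRIC_NAMES = ("acc", "aupr_micro", "auc_micro", "f1_macro", "pre_macro", "recall_macro")


class ValidationError(ValueError):
    """Raised when an input file or container violates an invariant."""


@dataclass
class DrugFeatureTable:
    """Binary descriptor matrix for one feature category (e.g. targets)."""

    category: str
    drug_ids: list[str]
    descriptors: list[str]
    values: np.ndarray  # (N, F) of {0,1}

    def __post_init__(self):
        self.values = np.asarray(self.values)
        n, f = self.values.shape
        if f == 0:
            raise ValidationError(f"{self.category}: no descriptors")
        if len(self.drug_ids) != n or len(self.descriptors) != f:
            raise ValidationError(f"{self.category}: shape/label mismatch")
        if len(set(self.drug_ids)) != n:
            raise ValidationError(f"{self.category}: duplicate drug id")
        if len(set(self.descriptors)) != f:
            raise ValidationError(f"{self.category}: duplicate descriptor name")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"{self.category}: non-binary entry {self.values[i, j]!r} at "
                f"row {self.drug_ids[i]!r}, column {self.descriptors[j]!r}"
            )
        self.values = self.values.astype(np.float64)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)


@dataclass
class DDIDataset:
    """Symmetric multirelational pair-label set over a fixed drug order.

    ``pairs`` holds (i, j, y) with i < j (unordered canonical form) and
    1-based event labels y in {1..C}.
    """

    drug_ids: list[str]
    pairs: list[tuple[int, int, int]]
    num_event_types: int

    def __post_init__(self):
        n = len(self.drug_ids)
        if len(set(self.drug_ids)) != n:
            raise ValidationError("duplicate drug id")
        canon: dict[tuple[int, int], int] = {}
        for i, j, y in self.pairs:
            if i == j:
                raise ValidationError(f"self-pair for drug {self.drug_ids[i]!r}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"pair index out of range: ({i},{j})")
            if not (1 <= y <= self.num_event_types):
                raise ValidationError(
                    f"label {y} outside 1..{self.num_event_types}"
                )
            key = (min(i, j), max(i, j))
            if key in canon and canon[key] != y:
                raise ValidationError(
                    f"conflicting labels for pair "
                    f"({self.drug_ids[key[0]]!r},{self.drug_ids[key[1]]!r}): "
                    f"{canon[key]} vs {y}"
                )
            canon[key] = y
        self.pairs = sorted((i, j, y) for (i, j), y in canon.items())

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    def pair_array(self) -> np.ndarray:
        """Pairs as an (L, 2) int array of drug indices."""
        return np.array([(i, j) for i, j, _ in self.pairs], dtype=np.intp).reshape(-1, 2)

    def label_array(self) -> np.ndarray:
        """1-based labels as an (L,) int array."""
        return np.array([y for _, _, y in self.pairs], dtype=np.intp)


@dataclass
class MetricsReport:
    """The six evaluation metrics, each a proportion in [0, 1]."""

    acc: float
    aupr_micro: float
    auc_micro: float
    f1_macro: float
    pre_macro: float
    recall_macro: float

    def __post_init__(self):
        for name in METRIC_NAMES:
            v = float(getattr(self, name))
            if not (0.0 <= v <= 1.0) or not np.isfinite(v):
                raise ValidationError(f"metric {name}={v} outside [0, 1]")
            setattr(self, name, v)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_feature_table(path, category: str) -> DrugFeatureTable:
    """Read one binary descriptor table (CSV or TSV, sniffed from the header)."""
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={0: str})
    if df.shape[1] < 2:
        raise ValidationError(f"{category}: no descriptors")
    drug_ids = df.iloc[:, 0].tolist()
    values = df.iloc[:, 1:].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{category}: non-numeric descriptor entries")
    return DrugFeatureTable(
        category=category,
        drug_ids=drug_ids,
        descriptors=[str(c) for c in df.columns[1:]],
        values=values,
    )


def align_tables(tables: list[DrugFeatureTable]) -> list[DrugFeatureTable]:
    """Reorder every table to the drug order of the first one.

    Every drug must appear in every category; extra or missing rows are
    validation errors, not silently dropped.
    """
    if not tables:
        raise ValidationError("no feature tables given")
    order = tables[0].drug_ids
    out = [tables[0]]
    for t in tables[1:]:
        if set(t.drug_ids) != set(order):
            missing = sorted(set(order) - set(t.drug_ids))[:3]
            extra = sorted(set(t.drug_ids) - set(order))[:3]
            raise ValidationError(
                f"{t.category}: drug set differs from {tables[0].category} "
                f"(missing {missing}, extra {extra})"
            )
        pos = {d: k for k, d in enumerate(t.drug_ids)}
        idx = [pos[d] for d in order]
        out.append(
            DrugFeatureTable(t.category, list(order), t.descriptors, t.values[idx])
        )
    return out


def read_ddi_edges(path, drug_ids: list[str], num_event_types: int | None = None) -> DDIDataset:
    """Read the labeled edge list and assemble a canonical dataset.

    Unordered duplicates collapse to one record; the same pair carrying two
    different labels is an error.  ``num_event_types`` defaults to the
    maximum observed label.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValidationError("edge list needs columns drug1, drug2, event")
    pos = {d: k for k, d in enumerate(drug_ids)}
    pairs = []
    for d1, d2, y in df.iloc[:, :3].itertuples(index=False):
        for d in (d1, d2):
            if d not in pos:
                raise ValidationError(f"unknown drug id {d!r}")
        y = int(y)
        pairs.append((pos[d1], pos[d2], y))
    c = num_event_types if num_event_types is not None else max(y for *_, y in pairs)
    return DDIDataset(drug_ids=list(drug_ids), pairs=pairs, num_event_types=c)


def write_metrics(report: MetricsReport, path) -> None:
    """Write the six metrics as ``name<TAB>value`` lines."""
    with open(path, "w") as fh:
        for name, value in report.as_dict().items():
            fh.write(f"{name}\t{value:.17g}\n")


def read_metrics(path) -> MetricsReport:
    values: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, value = line.rstrip("\n").split("\t")
            values[name] = float(value)
    if set(values) != set(METRIC_NAMES):
        raise ValidationError(f"metrics file keys {sorted(values)} != expected")
    return MetricsReport(**values)


def write_feature_table(table: DrugFeatureTable, path, sep: str = ",") -> None:
    df = pd.DataFrame(table.values.astype(int), columns=table.descriptors)
    df.insert(0, "drug_id", table.drug_ids)
    df.to_csv(path, sep=sep, index=False)


def write_ddi_edges(dataset: DDIDataset, path, sep: str = ",") -> None:
    rows = [
        (dataset.drug_ids[i], dataset.drug_ids[j], y) for i, j, y in dataset.pairs
    ]
    pd.DataFrame(rows, columns=["drug1", "drug2", "event"]).to_csv(
        path, sep=sep, index=False
    )
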