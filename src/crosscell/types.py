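"""Core domain types shared by every stage of the benchmark.

The central object is a :class:`Dataset`: a panel of cell types observed at a
common set of genomic loci, with a continuous activity matrix (loci x cell
types), a binarized high/low label matrix derived from it, and two feature
families — a locus-constant feature vector per locus (the stand-in for
nucleotide sequence, and the channel through which locus identity can leak
into a model) and a cell-type-specific feature vector per (locus, cell type)
pair (the stand-in for epigenomic signal tracks).

Matrices are stored as :class:`pandas.DataFrame` objects indexed by locus id
(rows) and cell type id (columns); feature arrays are dense numpy arrays with
the same row/column ordering as the matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "CellTypePanel",
    "FeatureBundle",
    "TruthRecord",
    "Dataset",
    "ValidationError",
    "validate_activity_matrix",
    "validate_label_matrix",
]


class ValidationError(ValueError):
    """A domain-type invariant was violated."""


@dataclass(frozen=True)
class Locus:
    """A genomic interval in BED convention: 0-based, half-open."""

    locus_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"{self.locus_id}: negative start {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"{self.locus_id}: end ({self.end}) must exceed start ({self.start})"
            )


def validate_loci(loci: Sequence[Locus]) -> None:
    """Check uniqueness of ids and non-overlap within each chromosome."""
    ids = [l.locus_id for l in loci]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate locus_id in locus list")
    by_chrom: dict[str, list[Locus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chromosome, []).append(l)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda l: l.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping loci on {chrom}: {a.locus_id} and {b.locus_id}"
                )


@dataclass(frozen=True)
class CellTypePanel:
    """An ordered panel of cell types, each assigned to one lineage group.

    Lineage groups encode relatedness among cell types (e.g., all immune
    lines in one group); the synthetic generator gives cell types in the
    same group a shared activity deviation, so within-group activity
    profiles correlate more strongly than across groups.
    """

    cell_type_ids: tuple[str, ...]
    lineage_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.cell_type_ids)) != len(self.cell_type_ids):
            raise ValidationError("duplicate cell type ids in panel")
        missing = [c for c in self.cell_type_ids if c not in self.lineage_of]
        if missing:
            raise ValidationError(f"cell types without a lineage group: {missing}")

    def __len__(self) -> int:
        return len(self.cell_type_ids)

    def lineage_members(self, lineage: str) -> list[str]:
        return [c for c in self.cell_type_ids if self.lineage_of[c] == lineage]

    @property
    def lineages(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cell_type_ids:
            seen.setdefault(self.lineage_of[c], None)
        return list(seen)


def validate_activity_matrix(values: pd.DataFrame) -> None:
    """An activity matrix must be dense, finite, and uniquely indexed."""
    if values.index.has_duplicates:
        raise ValidationError("duplicate locus_id rows in matrix")
    if values.columns.has_duplicates:
        raise ValidationError("duplicate cell_type_id columns in matrix")
    arr = values.to_numpy()
    if arr.size and not np.isfinite(arr).all():
        raise ValidationError("non-finite values in activity matrix")


def validate_label_matrix(labels: pd.DataFrame) -> None:
    """Labels must be 0/1 with both classes present in every column."""
    validate_activity_matrix(labels)
    arr = labels.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("label matrix entries must be 0 or 1")
    col_pos = arr.sum(axis=0)
    bad = [
        str(c)
        for c, s in zip(labels.columns, col_pos)
        if s == 0 or s == arr.shape[0]
    ]
    if bad:
        raise ValidationError(
            f"label matrix columns with a single class: {bad}"
        )


@dataclass
class FeatureBundle:
    """The two feature families offered to models.

    ``locus_features`` has one d_s-vector per locus and is *identical for a
    locus wherever it appears*, regardless of cell type — this constancy is
    the defining property of the memorization channel.  ``celltype_features``
    has one d_e-vector per (locus, cell type) pair, shaped
    (n_loci, n_cell_types, d_e), aligned with the matrix row/column order.
    """

    locus_features: np.ndarray  # (n_loci, d_s)
    celltype_features: np.ndarray  # (n_loci, n_cell_types, d_e)

    def __post_init__(self) -> None:
        if self.locus_features.ndim != 2:
            raise ValidationError("locus_features must be 2-D (loci x d_s)")
        if self.celltype_features.ndim != 3:
            raise ValidationError(
                "celltype_features must be 3-D (loci x cell types x d_e)"
            )
        if self.locus_features.shape[0] != self.celltype_features.shape[0]:
            raise ValidationError("feature families disagree on locus count")
        if not np.isfinite(self.locus_features).all():
            raise ValidationError("non-finite locus feature values")
        if not np.isfinite(self.celltype_features).all():
            raise ValidationError("non-finite cell-type feature values")

    @property
    def d_s(self) -> int:
        return self.locus_features.shape[1]

    @property
    def d_e(self) -> int:
        return self.celltype_features.shape[2]


@dataclass
class TruthRecord:
    """Latent generative state, retained for parameter-recovery tests.

    activity(l, c) = mu[l] + lineage_dev[l, lineage_of(c)] + cell_dev[l, c]
    and label(l, c) = 1 iff activity(l, c) > threshold_tau.
    """

    mu: pd.Series  # per locus
    lineage_dev: pd.DataFrame  # loci x lineage groups
    cell_dev: pd.DataFrame  # loci x cell types
    threshold_tau: float
    config: "object" = None  # GeneratorConfig; typed loosely to avoid a cycle


@dataclass
class Dataset:
    """A complete benchmark dataset; all components share index order."""

    loci: list[Locus]
    panel: CellTypePanel
    activity: pd.DataFrame  # loci x cell types, float
    labels: pd.DataFrame  # loci x cell types, int 0/1
    features: FeatureBundle
    truth: TruthRecord | None = None

    _locus_index: dict[str, int] = field(init=False, repr=False)
    _cell_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        validate_loci(self.loci)
        validate_activity_matrix(self.activity)
        validate_label_matrix(self.labels)
        locus_ids = [l.locus_id for l in self.loci]
        if list(self.activity.index) != locus_ids:
            raise ValidationError("activity rows do not match locus list order")
        if list(self.labels.index) != locus_ids:
            raise ValidationError("label rows do not match locus list order")
        cts = list(self.panel.cell_type_ids)
        if list(self.activity.columns) != cts or list(self.labels.columns) != cts:
            raise ValidationError("matrix columns do not match cell type panel")
        if self.features.locus_features.shape[0] != len(self.loci):
            raise ValidationError("locus_features row count mismatch")
        if self.features.celltype_features.shape[1] != len(cts):
            raise ValidationError("celltype_features column count mismatch")
        self._locus_index = {lid: i for i, lid in enumerate(locus_ids)}
        self._cell_index = {c: j for j, c in enumerate(cts)}

    @property
    def locus_ids(self) -> list[str]:
        return list(self.activity.index)

    @property
    def cell_type_ids(self) -> list[str]:
        return list(self.activity.columns)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_cell_types(self) -> int:
        return len(self.panel)

    def locus_row(self, locus_id: str) -> int:
        try:
            return self._locus_index[locus_id]
        except KeyError:
            raise KeyError(f"unknown locus_id {locus_id!r}") from None

    def cell_col(self, cell_type_id: str) -> int:
        try:
            return self._cell_index[cell_type_id]
        except KeyError:
            raise KeyError(f"unknown cell_type_id {cell_type_id!r}") from None

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.loci:
            seen.setdefault(l.chromosome, None)
        return list(seen)

    def loci_on(self, chromosomes: set[str] | Sequence[str]) -> list[str]:
        chromset = set(chromosomes)
        return [l.locus_id for l in self.loci if l.chromosome in chromset]
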