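"""Diagnostics that unmask locus memorization.

Two complementary tools:

* **Variability-partitioned evaluation** groups loci by how much their label
  (or activity) varies across the *training* cell types, then scores each
  group separately.  Within a group, and especially in the high-variability
  groups, the cross-cell-type average carries much less ranking information,
  so a model that only memorized average activity loses its apparent edge.
* **Delta-from-average target reformulation** rewrites the regression target
  as the residual from the per-locus training-panel average, so a model must
  learn cell-type-specific deviations — the part of the signal the average
  cannot supply — and the locus-constant component is handed to it for free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .metrics import PredictionSet, UndefinedMetricError, average_precision
from .types import ValidationError

__all__ = [
    "VariabilityPartition",
    "partition_by_variability",
    "evaluate_per_bin",
    "delta_target_transform",
]


@dataclass
class VariabilityPartition:
    """Quantile bins of per-locus across-cell-type variability.

    Variability is always computed from training cell types only, never from
    the target cell type, so the partition itself leaks nothing.
    """

    n_bins: int
    variability_of: pd.Series  # per locus, sample SD across training cell types
    bin_of: pd.Series  # per locus, int in [0, n_bins)
    bin_edges: np.ndarray  # interior quantile cut points, length n_bins - 1

    def __post_init__(self) -> None:
        if not self.variability_of.index.equals(self.bin_of.index):
            raise ValidationError("variability and bin assignments disagree on loci")
        if self.bin_of.min() < 0 or self.bin_of.max() >= self.n_bins:
            raise ValidationError("bin index out of range")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variability": self.variability_of, "bin": self.bin_of}
        ).rename_axis("locus_id")

    def write_tsv(self, path) -> None:
        """Serialize as TSV (locus_id, variability, bin)."""
        self.to_frame().to_csv(path, sep="\t")


def partition_by_variability(
    train_matrix: pd.DataFrame, n_bins: int = 4
) -> VariabilityPartition:
    """Assign loci to quantile bins of across-cell-type variability.

    Parameters
    ----------
    train_matrix
        Label (default usage) or activity matrix restricted to the training
        cell types; needs at least two columns for a sample SD.
    n_bins
        Number of quantile bins; ties at a bin edge go to the lower bin.
    """
    if train_matrix.shape[1] < 2:
        raise ValidationError("variability needs at least 2 training cell types")
    if n_bins < 2:
        raise ValidationError("n_bins must be at least 2")
    variability = train_matrix.astype(float).std(axis=1, ddof=1)
    if variability.nunique() < n_bins:
        raise ValidationError(
            f"degenerate binning: {variability.nunique()} distinct variability "
            f"values cannot fill {n_bins} bins"
        )
    edges = np.quantile(
        variability.to_numpy(), [i / n_bins for i in range(1, n_bins)]
    )
    # value strictly above an edge moves up; a tie stays in the lower bin
    bin_of = (variability.to_numpy()[:, None] > edges[None, :]).sum(axis=1)
    return VariabilityPartition(
        n_bins=n_bins,
        variability_of=variability,
        bin_of=pd.Series(bin_of, index=variability.index),
        bin_edges=edges,
    )


def evaluate_per_bin(
    preds: PredictionSet, partition: VariabilityPartition
) -> pd.DataFrame:
    """AP and prevalence per variability bin.

    Returns a rectangular frame with one row per bin (``bin``, ``n``,
    ``prevalence``, ``ap``).  A bin whose test labels are single-class has an
    undefined AP, reported as NaN — never dropped silently.  Empty bins get
    NaN for both prevalence and AP.
    """
    loci = [l for l, _ in preds.pairs]
    missing = [l for l in loci if l not in partition.bin_of.index]
    if missing:
        raise KeyError(f"predictions on loci without a bin: {missing[:5]}")
    bins = partition.bin_of.loc[loci].to_numpy()
    rows = []
    for b in range(partition.n_bins):
        mask = bins == b
        n = int(mask.sum())
        if n == 0:
            rows.append({"bin": b, "n": 0, "prevalence": np.nan, "ap": np.nan})
            continue
        labels = preds.labels[mask]
        prevalence = float(labels.mean())
        subset = PredictionSet(
            pairs=[p for p, m in zip(preds.pairs, mask) if m],
            scores=preds.scores[mask],
            labels=labels,
        )
        try:
            ap = average_precision(subset)
        except UndefinedMetricError:
            ap = np.nan
        rows.append({"bin": b, "n": n, "prevalence": prevalence, "ap": ap})
    return pd.DataFrame(rows)


def delta_target_transform(
    activity: pd.DataFrame, train_cell_types: Sequence[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Reformulate the target as the deviation from the per-locus average.

    Returns ``(residual, avg)`` with avg(l) the mean activity over the
    training cell types and residual(l, c) = activity(l, c) - avg(l) for
    every column of ``activity``, so ``avg + residual`` reconstructs the
    input exactly.
    """
    train_cell_types = list(train_cell_types)
    if not train_cell_types:
        raise ValidationError("need at least one training cell type")
    missing = [c for c in train_cell_types if c not in activity.columns]
    if missing:
        raise KeyError(f"cell types absent from matrix: {missing}")
    avg = activity[train_cell_types].mean(axis=1)
    residual = activity.sub(avg, axis=0)
    return residual, avg
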