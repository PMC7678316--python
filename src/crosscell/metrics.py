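"""Evaluation metrics and the two reference baselines.

Average precision (AP) — the area under the precision-recall step curve —
is the benchmark's single performance metric for the binary high/low labels.
Tied scores are handled as a block: precision and recall update once per
distinct score value, so AP is deterministic and invariant to input order.

Two baselines bracket every model:

* the *random baseline*, the expected AP of uniformly random scores, which
  equals the positive-class prevalence of the test set; and
* the *average-activity baseline*, which scores each locus by its mean
  activity across the training cell types.  This is the minimal competitor
  that any genuinely cell-type-aware model must beat: it uses no information
  about the target cell type at all, only the cross-cell-type average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PredictionSet",
    "UndefinedMetricError",
    "average_precision",
    "random_baseline_ap",
    "average_activity_scores",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (e.g., single-class labels)."""


@dataclass
class PredictionSet:
    """Scores and labels for an ordered list of (locus, cell type) pairs."""

    pairs: list[tuple[str, str]]
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        n = len(self.pairs)
        if self.scores.shape != (n,) or self.labels.shape != (n,):
            raise ValueError("pairs, scores, and labels must have equal length")
        if n and not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        if n and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def prevalence(self) -> float:
        return float(np.mean(self.labels))


def _check_two_classes(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.size == 0 or labels.min() == labels.max():
        raise UndefinedMetricError(
            "metric undefined: labels contain a single class"
        )


def average_precision(preds: PredictionSet) -> float:
    """Average precision of a prediction set.

    AP = sum_k (R_k - R_{k-1}) * P_k over distinct-score thresholds k, with
    tied scores processed as one block.  Requires both classes present.

    The block sum is accumulated as sum_k dTP_k * P_k and divided by the
    positive count once at the end, so a perfect ranking yields exactly 1.0.
    """
    _check_two_classes(preds.labels)
    # descending unique score blocks; np.unique sorts ascending
    uniq, inverse = np.unique(-preds.scores, return_inverse=True)
    n_blocks = uniq.size
    block_tp = np.bincount(inverse, weights=preds.labels, minlength=n_blocks)
    block_n = np.bincount(inverse, minlength=n_blocks)
    tp = np.cumsum(block_tp)
    seen = np.cumsum(block_n)
    ap = float(np.sum(block_tp * (tp / seen)))
    return ap / float(tp[-1])


def random_baseline_ap(labels: Sequence[int] | np.ndarray) -> float:
    """Expected AP of uniformly random scores: the positive prevalence.

    This is the analytic expectation and the floor of meaningful
    performance; any informative ranking must exceed it.
    """
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(np.mean(labels))


def average_activity_scores(
    matrix: pd.DataFrame,
    test_loci: Iterable[str],
    train_cell_types: Sequence[str] | None = None,
) -> pd.Series:
    """The average-activity baseline: mean training-panel value per locus.

    Parameters
    ----------
    matrix
        Activity (or label) matrix, loci x cell types.  If
        ``train_cell_types`` is given, the mean is taken over those columns
        only; otherwise over every column of ``matrix`` (i.e., the caller
        already restricted it to the training panel).
    test_loci
        Loci to score; each must be a row of ``matrix``.

    Returns
    -------
    pandas.Series
        score(l) = mean over training cell types of matrix[l, c], indexed by
        locus.  The score depends on the locus only, never on the cell type
        being predicted.
    """
    if train_cell_types is not None:
        train_cell_types = list(train_cell_types)
        if not train_cell_types:
            raise ValueError("training cell-type panel is empty")
        missing = [c for c in train_cell_types if c not in matrix.columns]
        if missing:
            raise KeyError(f"cell types absent from matrix: {missing}")
        matrix = matrix[train_cell_types]
    if matrix.shape[1] == 0:
        raise ValueError("training cell-type panel is empty")
    test_loci = list(test_loci)
    missing_loci = [l for l in test_loci if l not in matrix.index]
    if missing_loci:
        raise KeyError(f"loci absent from matrix: {missing_loci[:5]}")
    return matrix.loc[test_loci].mean(axis=1).astype(float)
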