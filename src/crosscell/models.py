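"""Interchangeable classifiers at graded capacity, with input ablations.

This module is the instrument for the memorization experiment.  A
:class:`ModelSpec` names one point of the sweep: a model family (two-hidden-
layer MLPs width-swept along a documented ladder, or gradient-boosted trees
swept by tree count), a feature mode (cell-type-specific features only,
locus-constant features only, or both), and an optional randomized-input
control that destroys any biological content of the locus features while
preserving their locus-constancy:

* ``permuted_locus_id`` — one seeded permutation reassigns the existing
  locus-feature vectors to different loci (same permutation for every cell
  type), so the marginal feature distribution is untouched;
* ``gaussian_locus_id`` — replaces the table with fresh standard-Normal
  vectors, one per locus, reused across cell types.

If capacity still buys cross-cell-type test AP under these controls, the
model is memorizing locus identity, not reading biology.

All non-capacity hyperparameters are frozen per family so that the capacity
index is the only varied axis.  Training is fully seeded: identical
(spec, split, dataset) triples give identical scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier

from .metrics import PredictionSet
from .splits import Split
from .types import Dataset, ValidationError

__all__ = [
    "ModelSpec",
    "MLP_WIDTHS",
    "GBT_TREES",
    "TrainingError",
    "count_parameters",
    "assemble_features",
    "fit_predict",
    "fit_predict_regression",
]

Family = Literal["mlp", "gbt"]
FeatureMode = Literal["epigenome_only", "locus_id_only", "both"]
Control = Literal["none", "permuted_locus_id", "gaussian_locus_id"]

#: Capacity ladders.  MLPs have two hidden layers of equal width; the top
#: width gives ~10^6 parameters, the desk-scale ceiling at which locus
#: memorization is already unmistakable.  GBTs are swept by tree count at
#: fixed depth.
MLP_WIDTHS: tuple[int, ...] = (4, 16, 64, 256, 1024)
GBT_TREES: tuple[int, ...] = (10, 50, 250, 1250)

# Frozen per-family training hyperparameters (capacity is the only knob).
_MLP_EPOCHS = 30
_MLP_BATCH = 256
_MLP_LR = 1e-3
_GBT_DEPTH = 4
_GBT_LR = 0.1


class TrainingError(ValueError):
    """Training is undefined for this input (e.g., single-class labels)."""


@dataclass(frozen=True)
class ModelSpec:
    """One point of the capacity sweep."""

    family: Family = "mlp"
    capacity_index: int = 0
    feature_mode: FeatureMode = "locus_id_only"
    control: Control = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        ladder = MLP_WIDTHS if self.family == "mlp" else GBT_TREES
        if self.family not in ("mlp", "gbt"):
            raise ValidationError(f"unknown model family {self.family!r}")
        if not (0 <= self.capacity_index < len(ladder)):
            raise ValidationError(
                f"capacity_index {self.capacity_index} outside ladder of {len(ladder)}"
            )
        if self.feature_mode not in ("epigenome_only", "locus_id_only", "both"):
            raise ValidationError(f"unknown feature_mode {self.feature_mode!r}")
        if self.control not in ("none", "permuted_locus_id", "gaussian_locus_id"):
            raise ValidationError(f"unknown control {self.control!r}")
        if self.control != "none" and self.feature_mode == "epigenome_only":
            raise ValidationError(
                "randomized-input controls act on locus features; "
                "feature_mode must include them"
            )

    @property
    def capacity(self) -> int:
        """Hidden width (mlp) or tree count (gbt) at this ladder rung."""
        ladder = MLP_WIDTHS if self.family == "mlp" else GBT_TREES
        return ladder[self.capacity_index]


def count_parameters(spec: ModelSpec, d_in: int) -> int:
    """Trainable-parameter count (mlp) or tree count (gbt complexity proxy).

    For a width-h two-hidden-layer MLP with one output unit:
    d_in*h + h  +  h*h + h  +  h + 1.
    """
    if spec.family == "gbt":
        return spec.capacity
    h = spec.capacity
    return d_in * h + h + h * h + h + h + 1


def _input_dim(dataset: Dataset, feature_mode: FeatureMode) -> int:
    if feature_mode == "epigenome_only":
        return dataset.features.d_e
    if feature_mode == "locus_id_only":
        return dataset.features.d_s
    return dataset.features.d_s + dataset.features.d_e


def _locus_feature_table(
    dataset: Dataset, control: Control, seed: int
) -> np.ndarray:
    """The (possibly control-randomized) locus-feature table, row per locus."""
    table = dataset.features.locus_features
    if control == "none":
        return table
    rng = np.random.default_rng(seed)
    if control == "permuted_locus_id":
        perm = rng.permutation(table.shape[0])
        return table[perm]
    # gaussian_locus_id: fresh vectors, one per locus, reused across cell types
    return rng.normal(0.0, 1.0, size=table.shape)


def assemble_features(
    dataset: Dataset,
    pairs: Sequence[tuple[str, str]],
    feature_mode: FeatureMode,
    control: Control = "none",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (one row per pair) and 0/1 label vector.

    The same ``seed`` must be used for the train and test halves of a split
    so both see the same control-randomized locus-feature table; the
    controls preserve the invariant that a given locus maps to one feature
    vector regardless of cell type.
    """
    rows = np.fromiter(
        (dataset.locus_row(l) for l, _ in pairs), dtype=np.intp, count=len(pairs)
    )
    cols = np.fromiter(
        (dataset.cell_col(c) for _, c in pairs), dtype=np.intp, count=len(pairs)
    )
    blocks: list[np.ndarray] = []
    if feature_mode in ("locus_id_only", "both"):
        blocks.append(_locus_feature_table(dataset, control, seed)[rows])
    if feature_mode in ("epigenome_only", "both"):
        blocks.append(dataset.features.celltype_features[rows, cols, :])
    X = np.concatenate(blocks, axis=1) if len(blocks) > 1 else blocks[0].copy()
    y = dataset.labels.to_numpy()[rows, cols]
    return X, y


def _make_estimator(spec: ModelSpec):
    if spec.family == "mlp":
        h = spec.capacity
        return MLPClassifier(
            hidden_layer_sizes=(h, h),
            activation="relu",
            solver="adam",
            alpha=1e-6,
            batch_size=_MLP_BATCH,
            learning_rate_init=_MLP_LR,
            max_iter=_MLP_EPOCHS,
            shuffle=True,
            early_stopping=False,
            n_iter_no_change=_MLP_EPOCHS,
            tol=0.0,
            random_state=spec.seed,
        )
    return XGBClassifier(
        n_estimators=spec.capacity,
        max_depth=_GBT_DEPTH,
        learning_rate=_GBT_LR,
        tree_method="hist",
        n_jobs=1,
        random_state=spec.seed,
        verbosity=0,
    )


def fit_predict_regression(
    spec: ModelSpec,
    split: Split,
    dataset: Dataset,
    target: Literal["activity", "delta"] = "activity",
) -> PredictionSet:
    """Train on a continuous target and score the split's test pairs.

    ``target="activity"`` regresses the raw activity value.
    ``target="delta"`` regresses the residual from the per-locus average over
    the split's training cell types (the delta-from-average reformulation);
    the average is added back to the test predictions, so the two variants
    produce scores on the same scale and differ only in what the model had
    to learn.  Labels in the returned set are the binary high/low calls, so
    either variant can be scored with average precision directly.
    """
    from .diagnostics import delta_target_transform

    train_pairs = sorted(split.train_pairs)
    test_pairs = sorted(split.test_pairs)
    train_cts = sorted(split.train_cell_types)
    residual, avg = delta_target_transform(dataset.activity, train_cts)
    target_matrix = residual if target == "delta" else dataset.activity

    X_train, _ = assemble_features(
        dataset, train_pairs, spec.feature_mode, spec.control, spec.seed
    )
    y_train = np.array([target_matrix.at[l, c] for l, c in train_pairs])
    X_test, y_labels = assemble_features(
        dataset, test_pairs, spec.feature_mode, spec.control, spec.seed
    )
    if spec.family == "mlp":
        from sklearn.neural_network import MLPRegressor

        h = spec.capacity
        est = MLPRegressor(
            hidden_layer_sizes=(h, h), activation="relu", solver="adam",
            alpha=1e-6, batch_size=_MLP_BATCH, learning_rate_init=_MLP_LR,
            max_iter=_MLP_EPOCHS, shuffle=True, early_stopping=False,
            n_iter_no_change=_MLP_EPOCHS, tol=0.0, random_state=spec.seed,
        )
    else:
        from xgboost import XGBRegressor

        est = XGBRegressor(
            n_estimators=spec.capacity, max_depth=_GBT_DEPTH,
            learning_rate=_GBT_LR, tree_method="hist", n_jobs=1,
            random_state=spec.seed, verbosity=0,
        )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X_train, y_train)
    scores = np.asarray(est.predict(X_test), dtype=float)
    if target == "delta":
        scores = scores + avg.loc[[l for l, _ in test_pairs]].to_numpy()
    return PredictionSet(pairs=list(test_pairs), scores=scores, labels=y_labels)


def fit_predict(spec: ModelSpec, split: Split, dataset: Dataset) -> PredictionSet:
    """Train the specified classifier on the split and score its test pairs.

    Pairs are processed in sorted order so results are reproducible across
    processes; scores are positive-class probabilities (AP needs a ranking,
    not hard calls).
    """
    train_pairs = sorted(split.train_pairs)
    test_pairs = sorted(split.test_pairs)
    X_train, y_train = assemble_features(
        dataset, train_pairs, spec.feature_mode, spec.control, spec.seed
    )
    if y_train.min() == y_train.max():
        raise TrainingError("training labels contain a single class")
    X_test, y_test = assemble_features(
        dataset, test_pairs, spec.feature_mode, spec.control, spec.seed
    )
    est = _make_estimator(spec)
    import warnings

    with warnings.catch_warnings():
        # the MLP runs a fixed epoch budget; the convergence warning is expected
        warnings.simplefilter("ignore")
        est.fit(X_train, y_train)
    scores = est.predict_proba(X_test)[:, 1]
    return PredictionSet(pairs=list(test_pairs), scores=scores, labels=y_test)
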