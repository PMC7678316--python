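"""Train/test split construction for the three evaluation schemes.

A split is an explicit set of (locus_id, cell_type_id) pairs for training
and for testing, so disjointness and leakage properties are machine-checkable
rather than implied by loop structure:

* ``cross_chromosome`` — train and test within one cell type, on disjoint
  chromosome sets.  Measures generalization to new loci only.
* ``cross_cell_type`` — train on other cell types at *all* loci, test on the
  held-out target cell type.  Test loci deliberately recur in training under
  other cell types: this recurrence is the memorization channel under study.
* ``hybrid`` — train on other cell types restricted to non-test chromosomes;
  test loci appear in no training pair under any cell type.

By default all three schemes share an identical test set (same target cell
type, same test chromosomes), so differences in test performance are
attributable to the training data alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .types import Dataset, ValidationError

__all__ = [
    "Split",
    "make_cross_chromosome_split",
    "make_cross_cell_type_split",
    "make_hybrid_split",
    "make_split",
    "write_split_tsv",
]

Scheme = Literal["cross_chromosome", "cross_cell_type", "hybrid"]

Pair = tuple[str, str]  # (locus_id, cell_type_id)


@dataclass(frozen=True)
class Split:
    """A named evaluation scheme with explicit train and test pair sets."""

    scheme: Scheme
    train_pairs: frozenset[Pair]
    test_pairs: frozenset[Pair]
    target_cell_type: str
    test_chromosomes: frozenset[str]

    def __post_init__(self) -> None:
        if self.train_pairs & self.test_pairs:
            raise ValidationError("train and test pairs overlap")
        if not self.train_pairs or not self.test_pairs:
            raise ValidationError("train and test sets must be nonempty")
        if any(c != self.target_cell_type for _, c in self.test_pairs):
            raise ValidationError("test pairs must all lie in the target cell type")

    @property
    def train_loci(self) -> frozenset[str]:
        return frozenset(l for l, _ in self.train_pairs)

    @property
    def test_loci(self) -> frozenset[str]:
        return frozenset(l for l, _ in self.test_pairs)

    @property
    def train_cell_types(self) -> frozenset[str]:
        return frozenset(c for _, c in self.train_pairs)


def _check_test_chromosomes(dataset: Dataset, test_chromosomes: Iterable[str]) -> frozenset[str]:
    chroms = frozenset(test_chromosomes)
    all_chroms = set(dataset.chromosomes())
    if not chroms:
        raise ValidationError("test_chromosomes must be nonempty")
    unknown = chroms - all_chroms
    if unknown:
        raise ValidationError(f"unknown chromosomes: {sorted(unknown)}")
    if chroms == all_chroms:
        raise ValidationError(
            "test_chromosomes cover every chromosome; training set would be empty"
        )
    return chroms


def make_cross_chromosome_split(
    dataset: Dataset, target_cell_type: str, test_chromosomes: Iterable[str]
) -> Split:
    """Within-cell-type split: held-out chromosomes form the test set."""
    dataset.cell_col(target_cell_type)
    chroms = _check_test_chromosomes(dataset, test_chromosomes)
    test_loci = set(dataset.loci_on(chroms))
    train = frozenset(
        (lid, target_cell_type) for lid in dataset.locus_ids if lid not in test_loci
    )
    test = frozenset((lid, target_cell_type) for lid in test_loci)
    return Split(
        scheme="cross_chromosome",
        train_pairs=train,
        test_pairs=test,
        target_cell_type=target_cell_type,
        test_chromosomes=chroms,
    )


def _check_train_cell_types(
    dataset: Dataset, train_cell_types: Iterable[str], target_cell_type: str
) -> list[str]:
    train_cts = list(train_cell_types)
    if not train_cts:
        raise ValidationError("train_cell_types must be nonempty")
    for c in train_cts:
        dataset.cell_col(c)
    if target_cell_type in train_cts:
        raise ValidationError(
            f"target cell type {target_cell_type!r} must not appear in train_cell_types"
        )
    dataset.cell_col(target_cell_type)
    return train_cts


def make_cross_cell_type_split(
    dataset: Dataset,
    train_cell_types: Iterable[str],
    target_cell_type: str,
    test_chromosomes: Iterable[str],
) -> Split:
    """Cross-cell-type split: train on other cell types at all loci.

    Every test locus also appears in training under other cell types — the
    deliberate leak channel this benchmark exists to expose.
    """
    train_cts = _check_train_cell_types(dataset, train_cell_types, target_cell_type)
    chroms = _check_test_chromosomes(dataset, test_chromosomes)
    train = frozenset((lid, c) for lid in dataset.locus_ids for c in train_cts)
    test = frozenset((lid, target_cell_type) for lid in dataset.loci_on(chroms))
    return Split(
        scheme="cross_cell_type",
        train_pairs=train,
        test_pairs=test,
        target_cell_type=target_cell_type,
        test_chromosomes=chroms,
    )


def make_hybrid_split(
    dataset: Dataset,
    train_cell_types: Iterable[str],
    target_cell_type: str,
    test_chromosomes: Iterable[str],
) -> Split:
    """Hybrid split: test loci unseen in any cell type, target cell unseen."""
    train_cts = _check_train_cell_types(dataset, train_cell_types, target_cell_type)
    chroms = _check_test_chromosomes(dataset, test_chromosomes)
    test_loci = set(dataset.loci_on(chroms))
    train = frozenset(
        (lid, c)
        for lid in dataset.locus_ids
        if lid not in test_loci
        for c in train_cts
    )
    test = frozenset((lid, target_cell_type) for lid in test_loci)
    return Split(
        scheme="hybrid",
        train_pairs=train,
        test_pairs=test,
        target_cell_type=target_cell_type,
        test_chromosomes=chroms,
    )


def make_split(
    dataset: Dataset,
    scheme: Scheme,
    target_cell_type: str,
    test_chromosomes: Iterable[str],
    train_cell_types: Iterable[str] | None = None,
) -> Split:
    """Dispatch to the named scheme constructor."""
    if scheme == "cross_chromosome":
        return make_cross_chromosome_split(dataset, target_cell_type, test_chromosomes)
    if train_cell_types is None:
        train_cell_types = [
            c for c in dataset.cell_type_ids if c != target_cell_type
        ]
    if scheme == "cross_cell_type":
        return make_cross_cell_type_split(
            dataset, train_cell_types, target_cell_type, test_chromosomes
        )
    if scheme == "hybrid":
        return make_hybrid_split(
            dataset, train_cell_types, target_cell_type, test_chromosomes
        )
    raise ValidationError(f"unknown scheme {scheme!r}")


def write_split_tsv(split: Split, path) -> None:
    """Serialize a split as an audit TSV (role, locus_id, cell_type_id)."""
    with open(path, "w") as fh:
        fh.write(f"# scheme={split.scheme}\ttarget={split.target_cell_type}\t"
                 f"test_chromosomes={','.join(sorted(split.test_chromosomes))}\n")
        fh.write("role\tlocus_id\tcell_type_id\n")
        for role, pairs in (("train", split.train_pairs), ("test", split.test_pairs)):
            for lid, ct in sorted(pairs):
                fh.write(f"{role}\t{lid}\t{ct}\n")
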