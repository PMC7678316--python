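"""Readers and writers for the on-disk interchange formats.

Loci travel as BED4 (chrom, start, end, name; tab-separated, 0-based
half-open, sorted by chromosome then start).  Matrices travel as TSV with a
header row of cell type ids and the locus id in the first column.  Activity
values are written with Python's shortest-round-trip float repr, so a
write→read cycle is bit-exact; labels are written as integers.

Readers validate and refuse malformed input — they never silently repair.
"""

from __future__ import annotations

import os
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .types import Locus, ValidationError, validate_activity_matrix, validate_label_matrix

__all__ = [
    "write_loci_bed",
    "read_loci_bed",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


class ParseError(ValueError):
    """A file did not conform to the expected dialect."""


def write_loci_bed(loci: Iterable[Locus], path: str | os.PathLike) -> None:
    """Write loci as a sorted BED4 file (no header)."""
    rows = sorted(loci, key=lambda l: (l.chromosome, l.start))
    with open(path, "w") as fh:
        for l in rows:
            fh.write(f"{l.chromosome}\t{l.start}\t{l.end}\t{l.locus_id}\n")


def read_loci_bed(path: str | os.PathLike) -> list[Locus]:
    """Parse a BED4 file written by :func:`write_loci_bed`.

    Raises :class:`ParseError` naming the offending line on malformed input
    and :class:`~crosscell.types.ValidationError` on invalid intervals.
    """
    loci: list[Locus] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}, {end_s!r}"
                ) from None
            loci.append(Locus(locus_id=name, chromosome=chrom, start=start, end=end))
    ids = [l.locus_id for l in loci]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate locus ids")
    return loci


def write_matrix_tsv(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a loci x cell-types matrix as TSV.

    Integer dtypes (label matrices) serialize as integers; floats use the
    shortest repr that round-trips exactly.
    """
    validate_activity_matrix(matrix)
    matrix.to_csv(path, sep="\t", index_label="locus_id")


def read_matrix_tsv(
    path: str | os.PathLike,
    kind: Literal["activity", "labels"] = "activity",
) -> pd.DataFrame:
    """Read a matrix TSV back; the exact inverse of :func:`write_matrix_tsv`.

    ``kind="labels"`` additionally enforces 0/1 entries (returned as int64)
    and both classes per column.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", index_col="locus_id", float_precision="round_trip"
        )
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate locus_id rows")
    if df.isna().any().any():
        raise ParseError(f"{path}: missing or ragged values")
    arr = df.to_numpy()
    if not np.isfinite(arr.astype(float, copy=False)).all():
        raise ValidationError(f"{path}: non-finite values")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    if kind == "labels":
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError(f"{path}: label entries must be 0 or 1")
        df = df.astype(np.int64)
        validate_label_matrix(df)
    else:
        df = df.astype(np.float64)
        validate_activity_matrix(df)
    return df
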