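"""Synthetic multi-cell-type benchmark generator.

The generator emulates the statistical signature of real epigenomes that
makes locus memorization profitable: the activity of a locus varies far less
across cell types than activity varies across loci.  Activity is an additive
Gaussian model,

    activity(l, c) = mu_l + lineage_dev(l, lineage(c)) + delta_{l,c}

with mu_l ~ N(0, sigma_locus^2) per locus, a lineage-shared deviation
~ N(0, sigma_lineage^2) per (locus, lineage group), and a cell-type-specific
deviation ~ N(0, sigma_cell^2) per (locus, cell type).  With the default
sigma_locus = 1 and sigma_cell = 0.3, within-locus variance is an order of
magnitude below between-locus variance.  Binary high/low labels are obtained
by thresholding at a single global quantile tau, the (1 - positive_fraction)
quantile of all activity values, so global label prevalence equals
positive_fraction almost exactly.

Two feature families accompany the activity matrix.  Locus features are
standard-Normal vectors drawn once per locus and reused verbatim for every
cell type — an information-free stand-in for nucleotide sequence whose only
usable content is locus identity.  Cell-type features are noisy linear
read-outs of the activity itself (track j = a_j * activity + noise), the
stand-in for same-cell-type epigenomic signal.

The order of random draws is part of the public contract (documented in
:func:`generate_dataset`), so a fixed seed reproduces a dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    CellTypePanel,
    Dataset,
    FeatureBundle,
    Locus,
    TruthRecord,
    ValidationError,
)

__all__ = ["GeneratorConfig", "ConfigError", "generate_dataset", "celltype_similarity", "PRESETS"]


class ConfigError(ValueError):
    """The generator configuration is degenerate or inconsistent."""


@dataclass(frozen=True)
class GeneratorConfig:
    """All stochastic-model parameters of the generator.

    Parameters
    ----------
    n_loci, n_chromosomes, n_cell_types, n_lineages
        Problem dimensions.  Loci are assigned to chromosomes in contiguous
        near-equal blocks; cell types to lineage groups likewise.
    sigma_locus
        SD of the per-locus mean activity mu_l (between-locus spread).
    sigma_lineage
        SD of the lineage-shared deviation; 0 disables lineage structure.
    sigma_cell
        SD of the cell-type-specific deviation (within-locus spread).
    positive_fraction
        Global label prevalence in (0, 1); 0.5 mimics a balanced high/low
        expression call, 0.05 a rare-event task such as TAD-boundary calling.
    d_s, d_e
        Locus-feature and cell-type-feature dimensions.
    epi_noise
        SD of the additive noise on each cell-type feature track.
    locus_width
        Width of each tiled genomic window, in bases.
    seed
        Seed for the single random stream all draws come from.
    """

    n_loci: int = 2000
    n_chromosomes: int = 5
    n_cell_types: int = 20
    n_lineages: int = 1
    sigma_locus: float = 1.0
    sigma_lineage: float = 0.0
    sigma_cell: float = 0.3
    positive_fraction: float = 0.5
    d_s: int = 32
    d_e: int = 8
    epi_noise: float = 1.0
    locus_width: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.n_loci < 1 or self.n_cell_types < 1:
            raise ConfigError("n_loci and n_cell_types must be positive")
        if not (1 <= self.n_chromosomes <= self.n_loci):
            raise ConfigError("need 1 <= n_chromosomes <= n_loci")
        if not (1 <= self.n_lineages <= self.n_cell_types):
            raise ConfigError("need 1 <= n_lineages <= n_cell_types")
        if not (0.0 < self.positive_fraction < 1.0):
            raise ConfigError("positive_fraction must lie strictly in (0, 1)")
        if self.positive_fraction * self.n_loci * self.n_cell_types < 1:
            raise ConfigError("positive_fraction too small for the matrix size")
        for name in ("sigma_locus", "sigma_lineage", "sigma_cell", "epi_noise"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.d_s < 1 or self.d_e < 1:
            raise ConfigError("feature dimensions must be positive")
        if self.locus_width < 1:
            raise ConfigError("locus_width must be positive")


#: Named parameter presets for the two tasks the benchmark emulates, plus a
#: lineage-structured variant used to study train/test cell-type similarity.
PRESETS: dict[str, GeneratorConfig] = {
    "expression": GeneratorConfig(positive_fraction=0.5),
    "tad": GeneratorConfig(positive_fraction=0.05),
    "lineage": GeneratorConfig(
        positive_fraction=0.5, n_lineages=4, sigma_lineage=0.5
    ),
}


def _contiguous_blocks(n_items: int, n_blocks: int) -> np.ndarray:
    """Block index per item; blocks contiguous with near-equal sizes."""
    sizes = np.full(n_blocks, n_items // n_blocks, dtype=int)
    sizes[: n_items % n_blocks] += 1
    return np.repeat(np.arange(n_blocks), sizes)


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Draw one complete dataset from the generative model.

    All randomness comes from a single ``numpy.random.default_rng(seed)``
    stream, consumed in this fixed order:

    1. loci -> chromosomes (deterministic contiguous blocks, no draws);
    2. mu_l ~ N(0, sigma_locus^2), one per locus;
    3. lineage deviations ~ N(0, sigma_lineage^2), (locus, lineage) grid;
    4. delta_{l,c} ~ N(0, sigma_cell^2), (locus, cell type) grid;
    5. activity = mu + lineage_dev + delta; tau = empirical
       (1 - positive_fraction) quantile of all activity; label = activity > tau;
    6. locus features ~ N(0, 1), (locus, d_s) grid, shared across cell types;
    7. track loadings a_j ~ Uniform(0.5, 1.5) (d_e draws), then track noise
       ~ N(0, epi_noise^2) on the (locus, cell type, d_e) grid.

    Raises
    ------
    ConfigError
        If the configuration is degenerate.
    ValidationError
        If a label column ends up single-class (all high or all low); the
        caller should adjust ``positive_fraction`` or the variance ratio.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # 1. coordinates: tiled fixed-width windows, contiguous chromosome blocks
    chrom_of = _contiguous_blocks(config.n_loci, config.n_chromosomes)
    loci: list[Locus] = []
    offset_within = 0
    prev_chrom = -1
    for i, ch in enumerate(chrom_of):
        if ch != prev_chrom:
            offset_within = 0
            prev_chrom = ch
        start = offset_within * config.locus_width
        loci.append(
            Locus(
                locus_id=f"L{i:05d}",
                chromosome=f"chr{ch + 1}",
                start=start,
                end=start + config.locus_width,
            )
        )
        offset_within += 1
    locus_ids = [l.locus_id for l in loci]

    cell_ids = [f"CT{j:02d}" for j in range(config.n_cell_types)]
    lineage_idx = _contiguous_blocks(config.n_cell_types, config.n_lineages)
    lineage_labels = [f"lineage{g + 1}" for g in range(config.n_lineages)]
    panel = CellTypePanel(
        cell_type_ids=tuple(cell_ids),
        lineage_of={c: lineage_labels[g] for c, g in zip(cell_ids, lineage_idx)},
    )

    # 2.-4. latent draws
    mu = rng.normal(0.0, config.sigma_locus, size=config.n_loci)
    lineage_dev = rng.normal(
        0.0, config.sigma_lineage, size=(config.n_loci, config.n_lineages)
    )
    cell_dev = rng.normal(
        0.0, config.sigma_cell, size=(config.n_loci, config.n_cell_types)
    )

    # 5. activity, threshold, labels
    activity = mu[:, None] + lineage_dev[:, lineage_idx] + cell_dev
    tau = float(np.quantile(activity, 1.0 - config.positive_fraction))
    labels = (activity > tau).astype(np.int64)

    # 6. locus-constant features (the memorization channel)
    locus_features = rng.normal(0.0, 1.0, size=(config.n_loci, config.d_s))

    # 7. cell-type-specific features: noisy linear read-outs of activity
    loadings = rng.uniform(0.5, 1.5, size=config.d_e)
    track_noise = rng.normal(
        0.0,
        config.epi_noise,
        size=(config.n_loci, config.n_cell_types, config.d_e),
    )
    celltype_features = loadings[None, None, :] * activity[:, :, None] + track_noise

    activity_df = pd.DataFrame(activity, index=locus_ids, columns=cell_ids)
    labels_df = pd.DataFrame(labels, index=locus_ids, columns=cell_ids)
    col_pos = labels_df.sum(axis=0)
    bad = [c for c in cell_ids if col_pos[c] in (0, len(locus_ids))]
    if bad:
        raise ValidationError(
            "generated label columns with a single class "
            f"({bad}); increase n_loci, positive_fraction, or sigma_locus"
        )

    truth = TruthRecord(
        mu=pd.Series(mu, index=locus_ids, name="mu"),
        lineage_dev=pd.DataFrame(lineage_dev, index=locus_ids, columns=lineage_labels),
        cell_dev=pd.DataFrame(cell_dev, index=locus_ids, columns=cell_ids),
        threshold_tau=tau,
        config=config,
    )
    return Dataset(
        loci=loci,
        panel=panel,
        activity=activity_df,
        labels=labels_df,
        features=FeatureBundle(
            locus_features=locus_features, celltype_features=celltype_features
        ),
        truth=truth,
    )


def celltype_similarity(dataset: Dataset, c1: str, c2: str) -> float:
    """Pearson correlation of the activity columns of two cell types.

    Quantifies how similar two cell types' activity profiles are; the
    strength of the average-activity baseline on a target cell type grows
    with its similarity to the training panel.
    """
    x = dataset.activity[c1].to_numpy()
    y = dataset.activity[c2].to_numpy()
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValidationError(
            f"correlation undefined: zero-variance activity column ({c1!r} or {c2!r})"
        )
    return float(np.corrcoef(x, y)[0, 1])


def preset_config(name: str, **overrides) -> GeneratorConfig:
    """Return a named preset, optionally with field overrides."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return replace(base, **overrides) if overrides else base
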