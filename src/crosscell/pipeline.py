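"""Experiment orchestration: the full scheme x model x seed grid.

``run_experiment`` generates one dataset, builds each requested evaluation
scheme on it (so scheme is the only varying factor between rows sharing a
model), fits every grid point at every seed, and attaches the random and
average-activity baselines to every row.  The canonical output is one flat
``results.tsv``; a report step turns it into trend statistics (Spearman rank
correlation of capacity vs test AP), baseline-dominance verdicts, and an
optional figure of AP against parameter count per scheme.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .diagnostics import evaluate_per_bin, partition_by_variability
from .generate import ConfigError, GeneratorConfig, generate_dataset
from .io import write_loci_bed, write_matrix_tsv
from .metrics import (
    PredictionSet,
    average_activity_scores,
    average_precision,
    random_baseline_ap,
)
from .models import GBT_TREES, MLP_WIDTHS, ModelSpec, count_parameters, fit_predict
from .splits import Scheme, Split, make_split, write_split_tsv
from .types import Dataset, ValidationError

__all__ = [
    "GridPoint",
    "ExperimentConfig",
    "default_grid",
    "run_experiment",
    "report",
    "capacity_trend",
]

log = logging.getLogger("crosscell")

ALL_SCHEMES: tuple[Scheme, ...] = ("cross_chromosome", "cross_cell_type", "hybrid")


@dataclass(frozen=True)
class GridPoint:
    """A ModelSpec template: everything but the training seed.

    ``schemes`` optionally restricts the template to a subset of the
    experiment's schemes; None means "run under every requested scheme".
    """

    family: str = "mlp"
    capacity_index: int = 0
    feature_mode: str = "locus_id_only"
    control: str = "none"
    schemes: tuple[Scheme, ...] | None = None

    def spec(self, seed: int) -> ModelSpec:
        return ModelSpec(
            family=self.family,
            capacity_index=self.capacity_index,
            feature_mode=self.feature_mode,
            control=self.control,
            seed=seed,
        )


def default_grid() -> list[GridPoint]:
    """The default experiment grid.

    Locus-ID-only MLPs (real, permuted, and Gaussian locus features) are
    swept over four widths under the cross-cell-type and hybrid schemes —
    the memorization probe and its randomized-input controls.  Epigenome-only
    MLPs run under the cross-chromosome and cross-cell-type schemes, and a
    gradient-boosted-tree ladder replicates the locus-ID sweep.
    """
    grid: list[GridPoint] = []
    leak_schemes: tuple[Scheme, ...] = ("cross_cell_type", "hybrid")
    for control in ("none", "permuted_locus_id", "gaussian_locus_id"):
        for ci in range(4):
            grid.append(
                GridPoint("mlp", ci, "locus_id_only", control, leak_schemes)
            )
    for ci in range(4):
        grid.append(
            GridPoint(
                "mlp", ci, "epigenome_only", "none",
                ("cross_chromosome", "cross_cell_type"),
            )
        )
    for ci in range(3):
        grid.append(GridPoint("gbt", ci, "locus_id_only", "none", ("cross_cell_type",)))
    return grid


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment end to end."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    schemes: tuple[Scheme, ...] = ALL_SCHEMES
    target_cell_type: str | None = None  # None -> first cell type in the panel
    train_cell_types: tuple[str, ...] | None = None  # None -> all non-target
    test_chromosomes: tuple[str, ...] | None = None  # None -> last chromosome
    model_grid: list[GridPoint] = field(default_factory=default_grid)
    n_seeds: int = 3
    diagnostics_on: bool = True
    n_bins: int = 4
    output_dir: str | None = None

    def validate(self) -> None:
        self.generator.validate()
        if not self.model_grid:
            raise ConfigError("model_grid must be nonempty")
        if self.n_seeds < 1:
            raise ConfigError("n_seeds must be positive")
        unknown = set(self.schemes) - set(ALL_SCHEMES)
        if unknown:
            raise ConfigError(f"unknown schemes: {sorted(unknown)}")
        if (
            self.target_cell_type is not None
            and self.train_cell_types is not None
            and self.target_cell_type in self.train_cell_types
        ):
            raise ConfigError("target cell type must not appear in train_cell_types")


def _resolve(config: ExperimentConfig, dataset: Dataset):
    target = config.target_cell_type or dataset.cell_type_ids[0]
    train_cts = (
        list(config.train_cell_types)
        if config.train_cell_types is not None
        else [c for c in dataset.cell_type_ids if c != target]
    )
    test_chroms = (
        list(config.test_chromosomes)
        if config.test_chromosomes is not None
        else [dataset.chromosomes()[-1]]
    )
    return target, train_cts, test_chroms


_BASE_COLUMNS = [
    "scheme", "family", "capacity_index", "capacity", "parameter_count",
    "feature_mode", "control", "seed", "status", "n_test", "ap",
    "random_baseline_ap", "average_activity_ap",
]


def _predictions_for(dataset: Dataset, split: Split, scores_by_locus: pd.Series) -> PredictionSet:
    pairs = sorted(split.test_pairs)
    labels = np.array(
        [dataset.labels.at[l, c] for l, c in pairs], dtype=np.int64
    )
    scores = scores_by_locus.loc[[l for l, _ in pairs]].to_numpy()
    return PredictionSet(pairs=pairs, scores=scores, labels=labels)


def run_experiment(
    config: ExperimentConfig, dataset: Dataset | None = None
) -> pd.DataFrame:
    """Run the full grid and return (and optionally write) the results table.

    The dataset is generated once (or passed in) and shared by every scheme.
    One row per (scheme, grid point, seed), plus one average-activity
    baseline row per scheme.  When ``config.output_dir`` is set, writes
    ``results.tsv``, split audit TSVs, and the dataset interchange files.
    Fully deterministic given the config: a rerun produces byte-identical
    output.  A failing grid cell is flushed as a FAILED row before the error
    (annotated with its grid coordinates) propagates.
    """
    config.validate()
    if dataset is None:
        log.info("generating dataset (seed=%d)", config.generator.seed)
        dataset = generate_dataset(config.generator)
    target, train_cts, test_chroms = _resolve(config, dataset)

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_loci_bed(dataset.loci, out_dir / "loci.bed")
        write_matrix_tsv(dataset.activity, out_dir / "activity.tsv")
        write_matrix_tsv(dataset.labels, out_dir / "labels.tsv")

    rows: list[dict] = []
    bin_cols: list[str] = (
        [f"ap_bin{b}" for b in range(config.n_bins)]
        + [f"prevalence_bin{b}" for b in range(config.n_bins)]
        if config.diagnostics_on
        else []
    )

    def flush() -> pd.DataFrame:
        df = pd.DataFrame(rows, columns=_BASE_COLUMNS + bin_cols)
        if out_dir is not None:
            df.to_csv(out_dir / "results.tsv", sep="\t", index=False)
        return df

    for scheme in config.schemes:
        t0 = time.monotonic()
        split = make_split(
            dataset, scheme, target, test_chroms,
            train_cell_types=None if scheme == "cross_chromosome" else train_cts,
        )
        if out_dir is not None:
            write_split_tsv(split, out_dir / f"split_{scheme}.tsv")

        test_pairs = sorted(split.test_pairs)
        test_loci = [l for l, _ in test_pairs]
        test_labels = np.array(
            [dataset.labels.at[l, c] for l, c in test_pairs], dtype=np.int64
        )
        rand_ap = random_baseline_ap(test_labels)
        baseline_cts = sorted(split.train_cell_types)
        baseline_scores = average_activity_scores(
            dataset.activity, test_loci, baseline_cts
        )
        baseline_preds = _predictions_for(dataset, split, baseline_scores)
        baseline_ap = average_precision(baseline_preds)

        partition = None
        if config.diagnostics_on and len(baseline_cts) >= 2:
            try:
                partition = partition_by_variability(
                    dataset.labels[baseline_cts], config.n_bins
                )
            except ValidationError as exc:
                # too few distinct variability levels for the requested bins;
                # diagnostics columns stay NaN rather than aborting the grid
                log.warning("[%s] variability partition skipped: %s", scheme, exc)

        def bin_fields(preds: PredictionSet) -> dict:
            fields = {c: np.nan for c in bin_cols}
            if partition is not None:
                per_bin = evaluate_per_bin(preds, partition)
                for _, r in per_bin.iterrows():
                    fields[f"ap_bin{int(r['bin'])}"] = r["ap"]
                    fields[f"prevalence_bin{int(r['bin'])}"] = r["prevalence"]
            return fields

        rows.append(
            {
                "scheme": scheme, "family": "baseline", "capacity_index": -1,
                "capacity": np.nan, "parameter_count": np.nan,
                "feature_mode": "average_activity", "control": "none",
                "seed": -1, "status": "ok", "n_test": len(test_pairs),
                "ap": baseline_ap, "random_baseline_ap": rand_ap,
                "average_activity_ap": baseline_ap,
                **bin_fields(baseline_preds),
            }
        )
        log.info(
            "[%s] split built: %d train / %d test pairs, baseline AP %.4f (%.1fs)",
            scheme, len(split.train_pairs), len(test_pairs), baseline_ap,
            time.monotonic() - t0,
        )

        for point in config.model_grid:
            if point.schemes is not None and scheme not in point.schemes:
                continue
            for seed in range(config.n_seeds):
                spec = point.spec(seed)
                d_in = {
                    "epigenome_only": dataset.features.d_e,
                    "locus_id_only": dataset.features.d_s,
                    "both": dataset.features.d_s + dataset.features.d_e,
                }[point.feature_mode]
                coords = dict(
                    scheme=scheme, family=point.family,
                    capacity_index=point.capacity_index,
                    capacity=spec.capacity,
                    parameter_count=count_parameters(spec, d_in),
                    feature_mode=point.feature_mode, control=point.control,
                    seed=seed,
                )
                t1 = time.monotonic()
                try:
                    preds = fit_predict(spec, split, dataset)
                    ap = average_precision(preds)
                except Exception as exc:
                    rows.append(
                        {**coords, "status": "FAILED", "n_test": len(test_pairs),
                         "ap": np.nan, "random_baseline_ap": rand_ap,
                         "average_activity_ap": baseline_ap,
                         **{c: np.nan for c in bin_cols}}
                    )
                    flush()
                    raise RuntimeError(f"grid cell failed at {coords}") from exc
                rows.append(
                    {**coords, "status": "ok", "n_test": len(test_pairs),
                     "ap": ap, "random_baseline_ap": rand_ap,
                     "average_activity_ap": baseline_ap, **bin_fields(preds)}
                )
                log.info(
                    "[%s] %s cap=%d %s control=%s seed=%d: AP=%.4f (%.1fs)",
                    scheme, point.family, spec.capacity, point.feature_mode,
                    point.control, seed, ap, time.monotonic() - t1,
                )
    return flush()


def capacity_trend(results: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho of capacity vs seed-averaged AP per model series.

    A series is one (scheme, family, feature_mode, control) combination;
    APs are averaged over seeds per capacity rung first, then correlated
    against the rung order.  Series with fewer than two rungs get NaN.
    """
    rows = []
    models = results[(results["family"] != "baseline") & (results["status"] == "ok")]
    for key, grp in models.groupby(["scheme", "family", "feature_mode", "control"]):
        mean_ap = grp.groupby("capacity_index")["ap"].mean().sort_index()
        if len(mean_ap) >= 2:
            rho = float(spearmanr(mean_ap.index, mean_ap.values).statistic)
        else:
            rho = np.nan
        rows.append(
            dict(
                zip(["scheme", "family", "feature_mode", "control"], key),
                n_capacities=len(mean_ap),
                spearman_rho=rho,
                ap_min=float(mean_ap.min()),
                ap_max=float(mean_ap.max()),
                ap_spread=float(mean_ap.max() - mean_ap.min()),
                trend_gain=float(mean_ap.iloc[-1] - mean_ap.iloc[0]),
            )
        )
    return pd.DataFrame(rows)


def report(results_path, plots: bool = False, plot_path=None) -> str:
    """Human-readable summary of a results.tsv: trends and verdicts.

    Prints, per model series, the Spearman capacity-AP trend, and per model
    row whether it beats the average-activity baseline — the comparison any
    cross-cell-type predictor must win before its AP means anything.
    """
    try:
        results = pd.read_csv(results_path, sep="\t")
    except Exception as exc:
        raise ValueError(f"malformed results file {results_path}: {exc}") from exc
    required = set(_BASE_COLUMNS)
    if not required.issubset(results.columns):
        raise ValueError(
            f"malformed results file {results_path}: missing columns "
            f"{sorted(required - set(results.columns))}"
        )
    lines: list[str] = []
    trends = capacity_trend(results)
    lines.append("Capacity trends (Spearman rho of capacity vs seed-mean AP):")
    if trends.empty:
        lines.append("  (no model rows)")
    for _, t in trends.iterrows():
        rho = "undefined" if np.isnan(t["spearman_rho"]) else f"{t['spearman_rho']:+.2f}"
        lines.append(
            f"  {t['scheme']:>17s} | {t['family']:>3s} | {t['feature_mode']:>14s}"
            f" | control={t['control']:<18s} rho={rho}"
            f" AP {t['ap_min']:.3f}..{t['ap_max']:.3f}"
        )
    lines.append("")
    lines.append("Baseline dominance (model beats average-activity baseline?):")
    models = results[results["family"] != "baseline"]
    for _, r in models.iterrows():
        verdict = "yes" if r["ap"] > r["average_activity_ap"] else "no"
        lines.append(
            f"  {r['scheme']:>17s} | {r['family']:>3s} cap={r['capacity']}"
            f" {r['feature_mode']} control={r['control']} seed={r['seed']}:"
            f" AP={r['ap']:.3f} vs baseline {r['average_activity_ap']:.3f} -> {verdict}"
        )
    if plots:
        path = _plot_results(results, plot_path or Path(results_path).with_suffix(".png"))
        lines.append(f"\nWrote figure: {path}")
    return "\n".join(lines)


def _plot_results(results: pd.DataFrame, path) -> str:
    """AP vs parameter count per scheme, one panel per scheme."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    schemes = [s for s in ALL_SCHEMES if s in set(results["scheme"])]
    fig, axes = plt.subplots(
        1, max(len(schemes), 1), figsize=(4.2 * max(len(schemes), 1), 3.4),
        sharey=True, squeeze=False,
    )
    colors = {"locus_id_only": "tab:blue", "epigenome_only": "tab:orange", "both": "tab:green"}
    for ax, scheme in zip(axes[0], schemes):
        sub = results[results["scheme"] == scheme]
        base = sub[sub["family"] == "baseline"]
        if not base.empty:
            ax.axhline(base["ap"].iloc[0], color="gold", lw=2, label="average activity")
            ax.axhline(base["random_baseline_ap"].iloc[0], color="gray", ls="--", label="random")
        for mode, grp in sub[sub["family"] != "baseline"].groupby("feature_mode"):
            ok = grp[grp["control"] == "none"]
            ax.scatter(
                ok["parameter_count"], ok["ap"], s=18, alpha=0.8,
                color=colors.get(mode, "k"), label=mode,
            )
        ax.set_xscale("log")
        ax.set_title(scheme)
        ax.set_xlabel("parameters")
    axes[0][0].set_ylabel("average precision")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)
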