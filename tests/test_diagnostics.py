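"""Variability partitioning and the delta-from-average reformulation."""

import numpy as np
import pandas as pd
import pytest

from crosscell.diagnostics import (
    delta_target_transform,
    evaluate_per_bin,
    partition_by_variability,
)
from crosscell.metrics import PredictionSet, average_precision
from crosscell.types import ValidationError


def labels_frame(rows, cts=("a", "b", "c", "d")):
    return pd.DataFrame(rows, index=[f"L{i}" for i in range(len(rows))],
                        columns=list(cts))


class TestPartition:
    def test_hand_crafted_matrix_bins_like_sort_and_cut_oracle(self):
        # 6 loci with known per-locus sample SDs, 2 bins
        m = labels_frame(
            [
                [0, 0, 0, 0],  # SD 0
                [1, 1, 1, 1],  # SD 0
                [1, 0, 0, 0],  # SD 0.5
                [1, 1, 0, 0],  # SD ~0.577
                [1, 0, 1, 0],  # SD ~0.577
                [0, 1, 1, 1],  # SD 0.5
            ]
        )
        part = partition_by_variability(m, n_bins=2)
        sds = m.std(axis=1, ddof=1)
        # independent oracle: sort loci by SD, cut at the median, tie -> low
        median = np.quantile(sds, 0.5)
        oracle = (sds > median).astype(int)
        assert part.bin_of.tolist() == oracle.tolist()
        assert np.allclose(part.variability_of, sds)

    def test_constant_locus_lands_in_lowest_bin(self):
        m = labels_frame([[0, 0, 0, 0], [1, 0, 0, 0], [1, 1, 0, 0], [1, 0, 1, 1]])
        part = partition_by_variability(m, n_bins=2)
        assert part.bin_of["L0"] == 0

    def test_variability_maximal_at_half_positive(self):
        m = labels_frame([[1, 1, 0, 0], [1, 0, 0, 0], [1, 1, 1, 0], [0, 0, 0, 1]])
        v = partition_by_variability(m, n_bins=2).variability_of
        assert v["L0"] == v.max()

    def test_partition_is_exhaustive_and_computed_from_train_only(self, small_dataset):
        train_cts = small_dataset.cell_type_ids[1:]
        part = partition_by_variability(small_dataset.labels[train_cts], n_bins=4)
        assert set(part.bin_of.index) == set(small_dataset.locus_ids)
        assert part.bin_of.isin(range(4)).all()
        # target column must not influence the statistic
        perturbed = small_dataset.labels.copy()
        perturbed[small_dataset.cell_type_ids[0]] = 1 - perturbed[
            small_dataset.cell_type_ids[0]
        ]
        part2 = partition_by_variability(perturbed[train_cts], n_bins=4)
        assert part.bin_of.equals(part2.bin_of)

    def test_single_training_cell_type_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            partition_by_variability(labels_frame([[0], [1]], cts=("a",)), 2)

    def test_degenerate_binning_rejected(self):
        m = labels_frame([[0, 0, 0, 0], [1, 1, 1, 1], [0, 0, 0, 0]])
        with pytest.raises(ValidationError, match="degenerate"):
            partition_by_variability(m, n_bins=2)


class TestEvaluatePerBin:
    def _preds(self, loci, scores, labels):
        return PredictionSet([(l, "T") for l in loci], np.array(scores), np.array(labels))

    def test_single_occupied_bin_equals_overall_ap(self):
        m = labels_frame([[0, 0, 0, 0], [1, 0, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0]])
        part = partition_by_variability(m, n_bins=2)
        low = [l for l in m.index if part.bin_of[l] == 0][:2]
        preds = self._preds(low, [0.9, 0.1], [1, 0])
        table = evaluate_per_bin(preds, part)
        assert table.loc[table["bin"] == 0, "ap"].iloc[0] == pytest.approx(
            average_precision(preds)
        )

    def test_empty_and_single_class_bins_marked_undefined_not_dropped(self):
        m = labels_frame([[0, 0, 0, 0], [1, 0, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0]])
        part = partition_by_variability(m, n_bins=2)
        preds = self._preds(["L0", "L1"], [0.2, 0.8], [1, 1])  # both in bin 0? no: L1 varies
        table = evaluate_per_bin(preds, part)
        assert len(table) == 2  # rectangular: every bin present
        assert table["ap"].isna().any()

    def test_bin_order_irrelevant(self, small_dataset):
        train_cts = small_dataset.cell_type_ids[1:]
        part = partition_by_variability(small_dataset.labels[train_cts], n_bins=3)
        target = small_dataset.cell_type_ids[0]
        loci = small_dataset.locus_ids
        rng = np.random.default_rng(0)
        preds = self._preds(loci, rng.uniform(size=len(loci)),
                            small_dataset.labels[target].to_numpy())
        t1 = evaluate_per_bin(preds, part)
        shuffled = PredictionSet(preds.pairs[::-1], preds.scores[::-1], preds.labels[::-1])
        t2 = evaluate_per_bin(shuffled, part)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unbinned_locus_rejected(self):
        m = labels_frame([[0, 0, 0, 0], [1, 0, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0]])
        part = partition_by_variability(m, n_bins=2)
        with pytest.raises(KeyError):
            evaluate_per_bin(self._preds(["L99"], [0.5], [1]), part)


class TestDeltaTransform:
    def test_reconstruction_identity(self, small_dataset):
        train = small_dataset.cell_type_ids[1:]
        residual, avg = delta_target_transform(small_dataset.activity, train)
        recon = residual.add(avg, axis=0)
        assert np.allclose(recon.to_numpy(), small_dataset.activity.to_numpy())

    def test_training_panel_residuals_mean_zero(self, small_dataset):
        train = small_dataset.cell_type_ids[1:]
        residual, _ = delta_target_transform(small_dataset.activity, train)
        assert np.allclose(residual[train].mean(axis=1).to_numpy(), 0.0)

    def test_flat_dataset_full_panel_residuals_vanish(self, flat_dataset):
        # identical columns: residuals are zero up to the rounding of the mean
        residual, _ = delta_target_transform(
            flat_dataset.activity, flat_dataset.cell_type_ids
        )
        assert np.abs(residual.to_numpy()).max() < 1e-12

    def test_empty_training_panel_rejected(self, small_dataset):
        with pytest.raises(ValidationError):
            delta_target_transform(small_dataset.activity, [])

    def test_delta_regression_non_inferior_to_raw_target_in_hybrid(self):
        """Regressing the residual from the training-panel average (then
        adding the average back) scores at least as well as regressing raw
        activity on held-out loci and cell type, within 0.02 AP over seeds."""
        from crosscell.generate import GeneratorConfig, generate_dataset
        from crosscell.models import ModelSpec, fit_predict_regression
        from crosscell.splits import make_split

        ds = generate_dataset(GeneratorConfig(seed=0))
        split = make_split(ds, "hybrid", ds.cell_type_ids[0], ["chr5"])
        raw, delta = [], []
        for seed in range(3):
            for kind, acc in (("activity", raw), ("delta", delta)):
                preds = fit_predict_regression(
                    ModelSpec("gbt", 1, "epigenome_only", "none", seed),
                    split, ds, target=kind,
                )
                acc.append(average_precision(preds))
        assert np.mean(delta) >= np.mean(raw) - 0.02


def test_partition_tsv_serialization(tmp_path, small_dataset):
    train_cts = small_dataset.cell_type_ids[1:]
    part = partition_by_variability(small_dataset.labels[train_cts], n_bins=3)
    path = tmp_path / "partition.tsv"
    part.write_tsv(path)
    lines = path.read_text().splitlines()
    assert lines[0] == "locus_id\tvariability\tbin"
    assert len(lines) == 1 + small_dataset.n_loci
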