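"""Average precision, the random baseline, and the average-activity baseline.

The AP oracle here is an independent direct implementation of the
precision-recall step sum with block tie handling; the package's own metric
must agree with it on every small configuration.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosscell.metrics import (
    PredictionSet,
    UndefinedMetricError,
    average_activity_scores,
    average_precision,
    random_baseline_ap,
)


def ap_oracle(scores, labels) -> float:
    """Brute-force AP: walk distinct score blocks from the top."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    n_pos = labels.sum()
    tp = fp = 0
    ap = 0.0
    prev_recall = 0.0
    for s in sorted(set(scores), reverse=True):
        block = scores == s
        tp += int(labels[block].sum())
        fp += int(block.sum() - labels[block].sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def ps(scores, labels):
    pairs = [(f"L{i}", "C") for i in range(len(scores))]
    return PredictionSet(pairs, np.asarray(scores, float), np.asarray(labels))


class TestAveragePrecision:
    def test_all_positives_ranked_first(self):
        assert average_precision(ps([0.9, 0.8, 0.7], [1, 1, 0])) == pytest.approx(1.0)

    def test_worked_example_seven_twelfths(self):
        # positives at ranks 2 and 3 contribute precisions 1/2 and 2/3
        assert average_precision(ps([0.9, 0.8, 0.7], [0, 1, 1])) == pytest.approx(7 / 12)

    def test_all_tied_scores_give_prevalence(self):
        assert average_precision(ps([0.5] * 8, [1, 0, 0, 1, 0, 0, 0, 0])) == pytest.approx(2 / 8)

    def test_order_of_input_is_irrelevant(self):
        a = average_precision(ps([0.1, 0.9, 0.5], [1, 0, 1]))
        b = average_precision(ps([0.9, 0.5, 0.1], [0, 1, 1]))
        assert a == pytest.approx(b)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            average_precision(ps([0.1, 0.2], [1, 1]))
        with pytest.raises(UndefinedMetricError):
            average_precision(ps([0.1, 0.2], [0, 0]))

    def test_matches_exhaustive_oracle_up_to_size_six(self):
        """Every label/score configuration of size <= 6 (3 score levels)."""
        checked = 0
        for n in range(2, 7):
            for scores in itertools.product((0.0, 0.5, 1.0), repeat=n):
                for labels in itertools.product((0, 1), repeat=n):
                    if 0 < sum(labels) < n:
                        got = average_precision(ps(scores, labels))
                        assert got == pytest.approx(ap_oracle(scores, labels)), (
                            scores, labels,
                        )
                        checked += 1
        assert checked > 10_000

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.tuples(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), st.integers(0, 1)),
            min_size=2, max_size=12,
        ).filter(lambda rows: 0 < sum(l for _, l in rows) < len(rows))
    )
    def test_oracle_agreement_property(self, rows):
        scores = [s for s, _ in rows]
        labels = [l for _, l in rows]
        assert average_precision(ps(scores, labels)) == pytest.approx(
            ap_oracle(scores, labels)
        )

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(st.sampled_from([-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0]),
                      st.integers(0, 1)),
            min_size=2, max_size=15,
        ).filter(lambda rows: 0 < sum(l for _, l in rows) < len(rows)),
        st.sampled_from([lambda x: 2 * x + 1, np.exp, lambda x: x**3 + 0.1 * x]),
    )
    def test_invariant_to_monotone_transform(self, rows, transform):
        scores = np.array([s for s, _ in rows])
        labels = [l for _, l in rows]
        before = average_precision(ps(scores, labels))
        after = average_precision(ps(transform(scores), labels))
        assert before == pytest.approx(after)

    def test_agrees_with_sklearn_on_random_inputs(self):
        """Independent library route: sklearn uses the same block formula."""
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(5, 60)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.uniform(size=n), rng.integers(1, 3))
            assert average_precision(ps(scores, labels)) == pytest.approx(
                average_precision_score(labels, scores)
            )

    def test_label_inversion_score_negation_symmetry(self):
        # complementary problem on a balanced, tie-free toy case
        scores = [0.9, 0.7, 0.5, 0.3]
        labels = [1, 0, 1, 0]
        flipped = average_precision(ps([-s for s in scores], [1 - l for l in labels]))
        assert flipped == pytest.approx(
            ap_oracle([-s for s in scores], [1 - l for l in labels])
        )


class TestRandomBaseline:
    def test_prevalence_by_definition(self):
        assert random_baseline_ap([1] * 5 + [0] * 95) == pytest.approx(0.05)
        assert random_baseline_ap([1] * 50 + [0] * 50) == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            random_baseline_ap([1, 1, 1])

    @staticmethod
    def exact_random_ap(n: int, n_pos: int) -> float:
        """Exact E[AP] under a uniformly random tie-free ranking.

        The rank K_i of the i-th best-ranked positive is negative
        hypergeometric; E[AP] = (1/P) sum_i i * E[1/K_i].  This is the
        finite-sample expectation, which exceeds prevalence slightly and
        converges to it as n grows.
        """
        from math import comb

        total = 0.0
        for i in range(1, n_pos + 1):
            for k in range(i, n - n_pos + i + 1):
                p_rank = comb(k - 1, i - 1) * comb(n - k, n_pos - i) / comb(n, n_pos)
                total += i / k * p_rank
        return total / n_pos

    def test_monte_carlo_mean_matches_exact_expectation(self):
        """MC mean AP of uniform-random scores hits the enumeration oracle.

        Also documents that the analytic floor returned by
        random_baseline_ap (the prevalence) is the large-n limit: the exact
        finite-n expectation sits slightly above it.
        """
        rng = np.random.default_rng(0)
        labels = np.array([1] * 10 + [0] * 30)
        prevalence = random_baseline_ap(labels)
        exact = self.exact_random_ap(n=40, n_pos=10)
        draws = [
            average_precision(ps(rng.uniform(size=labels.size), labels))
            for _ in range(2000)
        ]
        se = np.std(draws, ddof=1) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - exact) <= 3 * se
        assert exact > prevalence  # finite-sample bias of the step estimator
        # the bias vanishes with n: at 10x the size it is an order smaller
        assert self.exact_random_ap(400, 100) - 0.25 < (exact - 0.25) / 5


class TestAverageActivity:
    def test_single_training_cell_type_returns_its_column(self, small_dataset):
        ct = small_dataset.cell_type_ids[1]
        scores = average_activity_scores(
            small_dataset.activity, small_dataset.locus_ids, [ct]
        )
        assert np.array_equal(scores.to_numpy(), small_dataset.activity[ct].to_numpy())

    def test_label_matrix_rows_average(self):
        m = pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"], columns=["x", "y"])
        scores = average_activity_scores(m, ["a", "b"], ["x", "y"])
        assert list(scores) == [1.0, 0.0]

    def test_score_is_constant_across_target_cell_types(self, small_dataset):
        # the baseline never looks at the cell type being predicted
        scores = average_activity_scores(
            small_dataset.activity, small_dataset.locus_ids[:5],
            small_dataset.cell_type_ids[1:],
        )
        assert scores.index.tolist() == small_dataset.locus_ids[:5]

    def test_flat_dataset_baseline_is_perfect(self, flat_dataset):
        target = flat_dataset.cell_type_ids[0]
        train = flat_dataset.cell_type_ids[1:]
        loci = flat_dataset.locus_ids
        scores = average_activity_scores(flat_dataset.activity, loci, train)
        preds = PredictionSet(
            [(l, target) for l in loci],
            scores.to_numpy(),
            flat_dataset.labels[target].to_numpy(),
        )
        assert average_precision(preds) == 1.0

    def test_full_panel_mean_on_flat_dataset_reproduces_any_column(self, flat_dataset):
        scores = average_activity_scores(
            flat_dataset.activity, flat_dataset.locus_ids, flat_dataset.cell_type_ids
        )
        col = flat_dataset.activity[flat_dataset.cell_type_ids[0]]
        assert np.allclose(scores.to_numpy(), col.to_numpy())

    def test_empty_training_panel_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="empty"):
            average_activity_scores(small_dataset.activity, ["L00000"], [])

    def test_unknown_locus_rejected(self, small_dataset):
        with pytest.raises(KeyError):
            average_activity_scores(
                small_dataset.activity, ["nope"], small_dataset.cell_type_ids
            )
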