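"""Confusion matrices, one-vs-rest metrics, the accuracy identity, reports."""

import numpy as np
import pandas as pd
import pytest

import nirleaf as nl
from nirleaf.exceptions import ValidationError


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        labels = ["a", "b", "c"] * 4
        cm = nl.confusion(labels, labels, ("a", "b", "c"))
        assert np.array_equal(cm.counts, np.diag([4, 4, 4]))
        assert cm.micro_accuracy() == 1.0

    def test_row_sums_equal_class_sizes(self):
        rng = np.random.default_rng(0)
        order = ("a", "b", "c")
        true = rng.choice(order, size=60)
        assigned = rng.choice(order, size=60)
        cm = nl.confusion(true, assigned, order)
        for i, cls in enumerate(order):
            assert cm.counts[i].sum() == np.sum(true == cls)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        order = ("a", "b", "c", "d")
        true = rng.choice(order, size=80)
        assigned = rng.choice(order, size=80)
        cm = nl.confusion(true, assigned, order)
        for i, t in enumerate(order):
            for j, a in enumerate(order):
                naive = sum(
                    1 for x, y in zip(true, assigned) if x == t and y == a
                )
                assert cm.counts[i, j] == naive

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            nl.confusion(["a", "x"], ["a", "a"], ("a", "b"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            nl.confusion(["a"], ["a", "b"], ("a", "b"))


class TestPerClassMetrics:
    def test_guara_style_row(self):
        # TP=12, FN=3, FP=0, TN=75 in a 6-class test set of 90
        counts = np.zeros((6, 6), dtype=int)
        order = tuple("abcdef")
        counts[0, 0] = 12
        counts[0, 1] = 3
        for i in range(1, 6):
            counts[i, i] = 15
        cm = nl.ConfusionMatrix(counts=counts, class_order=order)
        df = nl.per_class_metrics(cm)
        row = df[df["class"] == "a"].iloc[0]
        assert row["sensitivity"] == pytest.approx(0.800)
        assert row["specificity"] == pytest.approx(1.000)
        assert 100 * row["accuracy"] == pytest.approx(96.7, abs=0.05)

    def test_perfect_matrix_all_ones(self):
        cm = nl.ConfusionMatrix(counts=np.diag([5, 5, 5]),
                                class_order=("a", "b", "c"))
        df = nl.per_class_metrics(cm)
        assert np.allclose(df[["sensitivity", "specificity", "accuracy"]], 1.0)

    def test_two_class_hand_computation(self):
        cm = nl.ConfusionMatrix(counts=np.array([[3, 1], [2, 4]]),
                                class_order=("x", "y"))
        row = nl.per_class_metrics(cm).iloc[0]
        assert row["sensitivity"] == pytest.approx(0.75)
        assert row["specificity"] == pytest.approx(4 / 6)
        assert row["accuracy"] == pytest.approx(0.7)

    def test_empty_class_row_yields_nan_not_zero(self):
        cm = nl.ConfusionMatrix(counts=np.array([[0, 0], [1, 3]]),
                                class_order=("x", "y"))
        row = nl.per_class_metrics(cm).iloc[0]
        assert np.isnan(row["sensitivity"])
        assert not np.isnan(row["specificity"])

    def test_micro_accuracy_complements_misassignment_rate(self):
        counts = np.array([[10, 2, 0], [1, 9, 2], [0, 0, 12]])
        cm = nl.ConfusionMatrix(counts=counts, class_order=("a", "b", "c"))
        mis = (counts.sum() - np.trace(counts)) / counts.sum()
        assert cm.micro_accuracy() == pytest.approx(1 - mis)


# Reported per-class rates of a published six-variety NIR study (one-vs-rest
# sensitivity, specificity, printed accuracy %) with 35/175 calibration and
# 15/75 test samples per class.  accuracy_from_rates must reproduce every
# printed accuracy to its one-decimal precision.  One table cell of the
# truncated fresh block prints a specificity (0.133) inconsistent with its
# own accuracy under the identity and is excluded as a typographical error.
TABLE_CELLS = [
    # full-spectrum model, dried-powdered block
    (0.971, 0.994, 35, 175, 99.0), (1.000, 0.973, 15, 75, 97.8),
    (0.829, 0.983, 35, 175, 95.7), (0.800, 1.000, 15, 75, 96.7),
    (0.971, 0.960, 35, 175, 96.2), (1.000, 0.973, 15, 75, 97.8),
    (0.971, 0.983, 35, 175, 98.1), (1.000, 1.000, 15, 75, 100.0),
    (0.886, 0.989, 35, 175, 97.1), (0.933, 0.987, 15, 75, 97.8),
    (0.886, 0.994, 35, 175, 97.6), (0.933, 1.000, 15, 75, 98.9),
    # full-spectrum model, fresh block
    (0.857, 0.977, 35, 175, 95.7), (1.000, 1.000, 15, 75, 100.0),
    (0.857, 0.943, 35, 175, 92.9), (0.600, 0.987, 15, 75, 92.2),
    (0.657, 0.943, 35, 175, 89.5), (0.867, 0.933, 15, 75, 92.2),
    (0.943, 0.994, 35, 175, 98.6), (1.000, 1.000, 15, 75, 100.0),
    (0.914, 0.983, 35, 175, 97.1), (1.000, 1.000, 15, 75, 100.0),
    (0.743, 0.954, 35, 175, 91.9), (0.933, 0.960, 15, 75, 95.6),
    # truncated model, dried-powdered block
    (0.971, 0.994, 35, 175, 99.0), (1.000, 0.973, 15, 75, 97.8),
    (0.829, 0.977, 35, 175, 95.2), (0.867, 0.987, 15, 75, 96.7),
    (0.914, 0.943, 35, 175, 93.8), (0.933, 0.987, 15, 75, 97.8),
    (1.000, 0.989, 35, 175, 99.0), (1.000, 1.000, 15, 75, 100.0),
    (0.886, 0.983, 35, 175, 96.7), (0.933, 1.000, 15, 75, 98.9),
    (0.800, 0.994, 35, 175, 96.2), (1.000, 1.000, 15, 75, 100.0),
    # truncated model, fresh block (typo cell excluded)
    (0.857, 0.977, 35, 175, 95.7), (1.000, 1.000, 15, 75, 100.0),
    (0.829, 0.943, 35, 175, 92.4), (0.600, 0.987, 15, 75, 92.2),
    (0.686, 0.949, 35, 175, 90.5), (0.867, 0.907, 15, 75, 90.0),
    (0.914, 0.983, 35, 175, 97.1), (1.000, 1.000, 15, 75, 100.0),
    (0.886, 0.971, 35, 175, 95.7),
    (0.743, 0.960, 35, 175, 92.4), (0.933, 0.960, 15, 75, 95.6),
]


@pytest.mark.parametrize("sens,spec,n_pos,n_neg,printed", TABLE_CELLS)
def test_accuracy_identity_reconstructs_printed_cells(sens, spec, n_pos,
                                                      n_neg, printed):
    value = nl.accuracy_from_rates(sens, spec, n_pos, n_neg)
    assert round(value, 1) == pytest.approx(printed, abs=0.05)


class TestReportRendering:
    @pytest.fixture()
    def report(self):
        order = ("a", "b", "c", "d", "e", "f")
        cm = nl.ConfusionMatrix(counts=np.diag([15] * 6), class_order=order)
        df = nl.per_class_metrics(cm)
        return nl.build_report(
            {"full_spectrum": {"cross_validation": df, "test": df},
             "truncated": {"cross_validation": df, "test": df}},
            n_lv={"full_spectrum": 9, "truncated": 7},
            n_variables={"full_spectrum": 2037, "truncated": 718},
        )

    def test_structure_24_rows(self, report):
        assert len(report) == 6 * 2 * 2
        assert list(report.columns) == list(nl.metrics.REPORT_COLUMNS)

    def test_text_formatting_one_decimal_percent(self, report):
        text = nl.format_report(report)
        assert "100.0%" in text

    def test_csv_round_trip(self, report, tmp_path):
        path = nl.metrics.write_report(report, tmp_path / "report.csv")
        back = pd.read_csv(path)
        assert np.allclose(back["accuracy_percent"],
                           report["accuracy_percent"])
        assert list(back["class"]) == list(report["class"])
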