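import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dtocrop.errors import ContractViolation
from dtocrop.metrics import (
    EvaluationReport,
    confusion_matrix,
    error_rate_fitness,
    macro_average,
    per_class_metrics,
    round_half_up,
)


def binary_metrics_oracle(tp, fp, fn, tn):
    """Independent transcription of the five one-vs-rest formulas (fractions)."""
    n = tp + fp + fn + tn
    acc = (tp + tn) / n if n else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return acc, prec, rec, f1, mcc


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 0, 1, 2, 2, 2])
        cm = confusion_matrix(y, y, 3)
        np.testing.assert_array_equal(cm, np.diag([2, 1, 3]))

    def test_hand_counted_two_class_example(self):
        cm = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_array_equal(cm, [[1, 1], [0, 1]])

    def test_matches_dictionary_counting_oracle(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        cm = confusion_matrix(y_true, y_pred, 4)
        counts = {}
        for t, p in zip(y_true, y_pred):
            counts[(t, p)] = counts.get((t, p), 0) + 1
        for i in range(4):
            for j in range(4):
                assert cm[i, j] == counts.get((i, j), 0)
        assert cm.sum() == 200

    def test_out_of_range_label_names_the_index(self):
        with pytest.raises(ContractViolation, match=r"y_pred\[2\]"):
            confusion_matrix([0, 0, 0], [0, 1, 5], 2)


class TestPerClassMetrics:
    def test_perfect_two_class_confusion_scores_100(self):
        table = per_class_metrics(np.array([[5, 0], [0, 5]]))
        for col in ("accuracy", "precision", "recall", "f_score", "mcc"):
            np.testing.assert_allclose(table[col], 100.0)

    def test_hand_evaluated_mixed_confusion(self):
        """[[4,1],[2,3]], class 0: TP=4 FP=2 FN=1 TN=3."""
        row = per_class_metrics(np.array([[4, 1], [2, 3]])).iloc[0]
        assert row["precision"] == pytest.approx(100 * 4 / 6, abs=0.005)
        assert row["recall"] == pytest.approx(80.0)
        assert row["f_score"] == pytest.approx(72.73, abs=0.005)
        assert row["accuracy"] == pytest.approx(70.0)
        assert row["mcc"] == pytest.approx(100 * 10 / np.sqrt(600), abs=1e-9)
        assert round_half_up(row["mcc"]) == 40.82

    def test_degenerate_predictions_flagged_not_raised(self):
        """All predictions in one class: the absent class has undefined
        precision, reported as 0 with a flag."""
        cm = confusion_matrix([0, 0, 1, 1], [0, 0, 0, 0], 2)
        table = per_class_metrics(cm)
        assert table.loc[1, "precision"] == 0.0
        assert "precision" in table.loc[1, "flags"]

    def test_counts_conserved_per_class(self):
        rng = np.random.default_rng(1)
        cm = rng.integers(0, 9, (5, 5))
        n = cm.sum()
        for k in range(5):
            tp = cm[k, k]
            fn = cm[k].sum() - tp
            fp = cm[:, k].sum() - tp
            tn = n - tp - fn - fp
            assert tp + fp + fn + tn == n

    def test_exhaustive_2x2_matches_oracle_and_mcc_bounded(self):
        for tp in range(6):
            for fp in range(6):
                for fn in range(6):
                    for tn in range(6):
                        if tp + fp + fn + tn == 0:
                            continue
                        cm = np.array([[tp, fn], [fp, tn]])
                        row = per_class_metrics(cm).iloc[0]
                        exp = binary_metrics_oracle(tp, fp, fn, tn)
                        got = [row[c] for c in ("accuracy", "precision", "recall", "f_score", "mcc")]
                        np.testing.assert_allclose(got, 100 * np.asarray(exp), atol=1e-9)
                        assert -100.0 <= row["mcc"] <= 100.0


class TestMacroAverage:
    def test_reproduces_printed_accuracy_average(self):
        table = pd.DataFrame({"accuracy": [97.71, 97.48, 98.08, 98.39, 98.02, 99.07]})
        assert macro_average(table)["accuracy"] == 98.13

    def test_reproduces_printed_precision_average(self):
        table = pd.DataFrame({"precision": [95.56, 94.83, 96.72, 91.73, 83.58, 95.52]})
        assert macro_average(table)["precision"] == 92.99

    def test_single_class_average_is_identity(self):
        table = pd.DataFrame({"recall": [87.5]})
        assert macro_average(table)["recall"] == 87.5

    def test_raw_average_equals_column_mean(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {c: rng.uniform(0, 100, 6) for c in ("accuracy", "precision", "recall", "f_score", "mcc")}
        )
        raw = macro_average(table, ndigits=None)
        for c in table.columns:
            assert raw[c] == pytest.approx(table[c].mean(), abs=1e-9)

    def test_display_rounding_is_half_up(self):
        assert round_half_up(98.125) == 98.13
        assert round_half_up(98.124999) == 98.12


class TestErrorRateFitness:
    def test_all_correct_is_zero(self):
        assert error_rate_fitness([1, 2, 3], [1, 2, 3]) == 0.0

    def test_one_wrong_of_four_is_25_percent(self):
        assert error_rate_fitness([0, 0, 1, 1], [0, 0, 1, 0]) == 25.0

    def test_empty_input_rejected(self):
        with pytest.raises(ContractViolation):
            error_rate_fitness([], [])

    @settings(max_examples=500, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_complementary_to_micro_accuracy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 50))
        y_true = rng.integers(0, 4, n)
        y_pred = rng.integers(0, 4, n)
        micro_acc = 100.0 * np.mean(y_true == y_pred)
        assert error_rate_fitness(y_true, y_pred) + micro_acc == pytest.approx(100.0)


class TestEvaluationReport:
    def test_report_structure_and_average_row(self):
        y_true = [0, 0, 0, 1, 1, 2, 2, 2]
        y_pred = [0, 0, 1, 1, 1, 2, 2, 0]
        rep = EvaluationReport.from_predictions(y_true, y_pred, ["a", "b", "c"], "TR80")
        assert rep.n_samples == 8
        assert rep.confusion.sum() == 8
        frame = rep.to_frame()
        assert list(frame["class"]) == ["a", "b", "c", "Average"]
        avg_row = frame.iloc[-1]
        for c in ("accuracy", "precision", "recall", "f_score", "mcc"):
            assert avg_row[c] == round_half_up(rep.per_class[c].mean())

    def test_report_csv_roundtrip(self, tmp_path):
        rep = EvaluationReport.from_predictions([0, 1], [0, 1], ["x", "y"], "TS20")
        rep.to_csv(tmp_path / "rep.csv")
        back = pd.read_csv(tmp_path / "rep.csv")
        assert back.iloc[-1]["accuracy"] == 100.0
        rep.confusion_to_csv(tmp_path / "cm.csv")
        cm = pd.read_csv(tmp_path / "cm.csv", index_col=0)
        np.testing.assert_array_equal(cm.to_numpy(), np.eye(2, dtype=int))
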