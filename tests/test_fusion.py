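"""Majority-vote fusion and multiclass metrics."""

import itertools

import numpy as np
import pytest

from accelhar.activities import ACTIVITY_CLASSES
from accelhar.fusion import (
    ClassificationReport,
    averaged_metrics,
    class_weights,
    confusion,
    majority_vote,
    per_class_metrics,
)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "triple, expected",
        [(("A3", "A3", "A4"), "A3"), (("A5", "A5", "A5"), "A5"), (("A1", "A2", "A3"), "A3")],
    )
    def test_examples(self, triple, expected):
        assert majority_vote(*triple) == expected

    def test_two_agreeing_pipelines_always_win(self):
        """Exhaustive over all label triples: with a 2-of-3 majority the
        vote returns it regardless of argument order; three-way
        disagreements go to the third pipeline."""
        labels = ACTIVITY_CLASSES
        for l1, l2, l3 in itertools.product(labels, repeat=3):
            got = majority_vote(l1, l2, l3)
            counts = {lab: (l1, l2, l3).count(lab) for lab in {l1, l2, l3}}
            best = max(counts.values())
            if best >= 2:
                winners = [lab for lab, c in counts.items() if c == best]
                assert got == winners[0]
            else:
                assert got == l3


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion(["A3", "A4"], ["A3", "A4"])
        assert cm.sum() == 2
        assert cm[2, 2] == 1 and cm[3, 3] == 1

    def test_hand_counted_entries(self):
        cm = confusion(["A3", "A3", "A4"], ["A3", "A4", "A4"])
        i3, i4 = ACTIVITY_CLASSES.index("A3"), ACTIVITY_CLASSES.index("A4")
        assert cm[i3, i3] == 1 and cm[i3, i4] == 1 and cm[i4, i4] == 1
        assert cm.sum() == 3

    def test_length_mismatch_and_stray_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion(["A3"], ["A3", "A4"])
        with pytest.raises(ValueError):
            confusion(["A3"], ["not-a-class"])


class TestPerClassMetrics:
    def test_precision_recall_f1_worked_example(self):
        """P = 1.00, R = 0.67 combine to F1 = 0.80 at two decimals."""
        pc = per_class_metrics(np.array([[4, 2], [0, 1]]), class_order=("x", "y"))
        assert pc.loc["x", "precision"] == pytest.approx(1.0)
        assert pc.loc["x", "recall"] == pytest.approx(4 / 6, abs=5e-3)
        assert round(pc.loc["x", "f1"], 2) == 0.80

    def test_perfect_diagonal(self):
        pc = per_class_metrics(np.diag([5, 3, 2]), class_order=("a", "b", "c"))
        assert (pc[["precision", "recall", "f1"]] == 1.0).all().all()

    def test_two_class_hand_computation(self):
        pc = per_class_metrics(np.array([[5, 1], [2, 2]]), class_order=("a", "b"))
        assert pc.loc["a", "precision"] == pytest.approx(5 / 7)
        assert pc.loc["a", "recall"] == pytest.approx(5 / 6)
        assert pc.loc["a", "f1"] == pytest.approx(2 * (5 / 7) * (5 / 6) / (5 / 7 + 5 / 6))
        assert pc.loc["a", "support"] == 6

    def test_absent_class_metrics_default_to_zero(self):
        pc = per_class_metrics(np.array([[3, 0], [0, 0]]), class_order=("a", "b"))
        assert pc.loc["b", "precision"] == 0.0
        assert pc.loc["b", "recall"] == 0.0
        assert pc.loc["b", "f1"] == 0.0


class TestAveragedMetrics:
    def test_equal_supports_make_weighted_equal_macro(self):
        cm = np.array([[8, 2, 0], [1, 9, 0], [0, 3, 7]])
        pc = per_class_metrics(cm, class_order=("a", "b", "c"))
        # equal supports of 10
        macro = averaged_metrics(pc, "macro")
        weighted = averaged_metrics(pc, "weighted")
        assert macro == pytest.approx(weighted)

    def test_micro_equals_accuracy(self):
        cm = np.array([[8, 2, 0], [1, 9, 0], [0, 3, 7]])
        pc = per_class_metrics(cm, class_order=("a", "b", "c"))
        p, r, f1 = averaged_metrics(pc, "micro")
        acc = np.trace(cm) / cm.sum()
        assert p == pytest.approx(acc) and r == pytest.approx(acc) and f1 == pytest.approx(acc)

    def test_macro_f1_conventions_differ(self):
        cm = np.array([[10, 0, 0], [8, 2, 0], [0, 0, 5]])
        pc = per_class_metrics(cm, class_order=("a", "b", "c"))
        _, _, f1_mean = averaged_metrics(pc, "macro", macro_f1="mean")
        p, r, f1_harm = averaged_metrics(pc, "macro", macro_f1="harmonic")
        assert f1_mean == pytest.approx(float(pc["f1"].mean()))
        assert f1_harm == pytest.approx(2 * p * r / (p + r))

    def test_zero_support_rejected(self):
        pc = per_class_metrics(np.zeros((2, 2), dtype=int), class_order=("a", "b"))
        with pytest.raises(ValueError):
            averaged_metrics(pc, "macro")


class TestClassWeights:
    def test_balanced_classes_weight_one(self):
        w = class_weights(["a"] * 20 + ["b"] * 20)
        assert w == {"a": 1.0, "b": 1.0}

    def test_inverse_frequency(self):
        w = class_weights(["a"] * 10 + ["b"] * 30)
        assert w["a"] == pytest.approx(2.0)
        assert w["b"] == pytest.approx(2 / 3)

    def test_rarest_class_has_largest_weight(self, rng):
        labels = rng.choice(["a", "b", "c"], p=[0.6, 0.3, 0.1], size=500)
        w = class_weights(labels)
        counts = {c: (labels == c).sum() for c in "abc"}
        rarest = min(counts, key=counts.get)
        assert w[rarest] == max(w.values())


class TestReport:
    def test_identities_on_generated_report(self, rng):
        true = rng.choice(ACTIVITY_CLASSES, size=300)
        pred = np.where(rng.random(300) < 0.7, true, rng.choice(ACTIVITY_CLASSES, size=300))
        rep = ClassificationReport.from_predictions(true, pred)
        assert rep.confusion_matrix.sum() == 300
        p, r, f1 = rep.micro_avg
        assert p == pytest.approx(rep.accuracy)
        assert r == pytest.approx(rep.accuracy)
        assert f1 == pytest.approx(rep.accuracy)
        # weighted recall is accuracy
        assert rep.weighted_avg[1] == pytest.approx(rep.accuracy)
        # supports are confusion row sums
        np.testing.assert_array_equal(
            rep.per_class["support"].to_numpy(), rep.confusion_matrix.sum(axis=1)
        )

    def test_text_report_renders(self):
        rep = ClassificationReport.from_predictions(["A3", "A4"], ["A3", "A4"])
        text = rep.to_text()
        assert "walk" in text and "accuracy" in text
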