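import random

import pytest

from rovannot.boxes import BBox
from rovannot.errors import ValidationError
from rovannot.evaluation import (
    ConfusionMatrix2x2,
    accuracy,
    best_threshold,
    confusion_2x2,
    detection_metrics,
    detection_metrics_oracle,
    load_clip_agreement_matrices,
    load_ml_confidence_matrices,
    read_matrices_csv,
)


class TestConfusion2x2:
    def test_perfect_agreement(self):
        labels = {f"u{i}": "Coral" if i % 2 else "NoCoral" for i in range(20)}
        m = confusion_2x2(labels, labels, "Coral")
        assert (m.fn, m.fp) == (0, 0) and m.total == 20

    def test_case_study_cells(self):
        expert = {}
        predicted = {}
        i = 0
        for e, p, n in [("Coral", "Coral", 52), ("Coral", "NoCoral", 17),
                        ("NoCoral", "Coral", 5), ("NoCoral", "NoCoral", 58)]:
            for _ in range(n):
                expert[f"u{i}"] = e
                predicted[f"u{i}"] = p
                i += 1
        m = confusion_2x2(expert, predicted, "Coral")
        assert (m.tp, m.fn, m.fp, m.tn) == (52, 17, 5, 58)
        assert m.total == 132

    def test_all_predicted_positive(self):
        expert = {"a": "Coral", "b": "NoCoral"}
        predicted = {"a": "Coral", "b": "Coral"}
        m = confusion_2x2(expert, predicted, "Coral")
        assert (m.fn, m.tn) == (0, 0)

    def test_unit_mismatch_lists_difference(self):
        with pytest.raises(ValidationError, match="b"):
            confusion_2x2({"a": "x"}, {"b": "x"}, "x")

    def test_permutation_invariance(self):
        rng = random.Random(0)
        units = [f"u{i}" for i in range(50)]
        expert = {u: rng.choice(["P", "N"]) for u in units}
        pred = {u: rng.choice(["P", "N"]) for u in units}
        m1 = confusion_2x2(expert, pred, "P")
        shuffled = dict(sorted(expert.items(), key=lambda kv: rng.random()))
        m2 = confusion_2x2(shuffled, pred, "P")
        assert m1 == m2


class TestAccuracy:
    @pytest.mark.parametrize(
        "cells, expected",
        [((10, 0, 0, 10), 1.0), ((52, 17, 5, 58), 110 / 132), ((0, 5, 0, 5), 0.5)],
    )
    def test_values(self, cells, expected):
        assert accuracy(ConfusionMatrix2x2(*cells)) == pytest.approx(expected)

    def test_empty_matrix_undefined(self):
        with pytest.raises(ValidationError):
            accuracy(ConfusionMatrix2x2(0, 0, 0, 0))


class TestBestThreshold:
    def test_case_study_selects_07(self):
        mats = load_ml_confidence_matrices()
        accs = {t: accuracy(m) for t, m in mats.items()}
        assert accs == pytest.approx({0.5: 104 / 132, 0.7: 110 / 132, 0.9: 90 / 132})
        assert best_threshold(mats) == 0.7

    def test_single_entry_and_tie_rule(self):
        m = ConfusionMatrix2x2(5, 1, 1, 5)
        assert best_threshold({0.3: m}) == 0.3
        assert best_threshold({0.3: m, 0.8: m}) == 0.8  # tie -> higher

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            best_threshold({})


class TestBundledMatrices:
    def test_clip_matrices_sum_to_2594(self):
        mats = load_clip_agreement_matrices()
        assert set(mats) == {0.4, 0.6, 0.8}
        assert all(m.total == 2594 for m in mats.values())

    def test_square_matrices_sum_to_132(self):
        mats = load_ml_confidence_matrices()
        assert set(mats) == {0.5, 0.7, 0.9}
        assert all(m.total == 132 for m in mats.values())

    def test_citizen_coral_counts_monotone_in_threshold(self):
        # pipeline-positive counts must grow as the agreement bar drops
        mats = load_clip_agreement_matrices()
        positives = {t: m.tp + m.fp for t, m in mats.items()}
        assert positives[0.8] < positives[0.6] < positives[0.4]
        assert positives == {0.8: 113, 0.6: 337, 0.4: 559}
        fps = {t: m.fp for t, m in mats.items()}
        assert fps[0.8] < fps[0.6] < fps[0.4]

    def test_machine_coral_counts_monotone_in_confidence(self):
        mats = load_ml_confidence_matrices()
        positives = {t: m.tp + m.fp for t, m in mats.items()}
        assert positives[0.9] < positives[0.7] < positives[0.5]
        assert positives == {0.5: 67, 0.7: 57, 0.9: 29}

    def test_round_trip_through_csv(self, tmp_path):
        import pandas as pd

        mats = load_ml_confidence_matrices()
        rows = []
        for t, m in mats.items():
            rows += [
                (t, "Coral", "Coral", m.tp), (t, "Coral", "NoCoral", m.fn),
                (t, "NoCoral", "Coral", m.fp), (t, "NoCoral", "NoCoral", m.tn),
            ]
        path = tmp_path / "m.csv"
        pd.DataFrame(rows, columns=["conf_threshold", "expert_label",
                                    "predicted_label", "count"]).to_csv(path, index=False)
        assert read_matrices_csv(path, "conf_threshold") == mats


class TestDetectionMetrics:
    T = BBox(0, 0, 50, 50)

    def test_perfect_predictions(self):
        m = detection_metrics([(self.T, 0.9)], [self.T])
        assert (m.precision, m.recall, m.f1, m.ap50) == (1.0, 1.0, 1.0, 1.0)

    def test_half_recall(self):
        truth = [self.T, BBox(200, 200, 50, 50)]
        m = detection_metrics([(self.T, 0.9)], truth)
        assert (m.precision, m.recall) == (1.0, 0.5)
        assert m.f1 == pytest.approx(2 / 3)

    def test_confident_hit_then_miss(self):
        preds = [(self.T, 0.9), (BBox(300, 300, 10, 10), 0.8)]
        m = detection_metrics(preds, [self.T])
        assert m.precision == 0.5 and m.ap50 == 1.0

    def test_miss_then_confident_hit_lowers_ap(self):
        preds = [(BBox(300, 300, 10, 10), 0.9), (self.T, 0.8)]
        m = detection_metrics(preds, [self.T])
        assert m.ap50 == pytest.approx(0.5)  # hit arrives at rank 2

    def test_edge_conventions(self):
        assert detection_metrics([], []) == detection_metrics_oracle([], [])
        m = detection_metrics([(self.T, 0.9)], [])
        assert m.precision == 0.0 and m.ap50 == 0.0
        m = detection_metrics([], [self.T])
        assert m.recall == 0.0 and m.ap50 == 0.0

    def test_exhaustive_oracle_equivalence_on_disjoint_truths(self):
        rng = random.Random(8)
        for _ in range(300):
            truth = [
                BBox(120 * i, 0, 40 + rng.randint(0, 30), 40 + rng.randint(0, 30))
                for i in range(rng.randint(0, 4))
            ]
            preds = []
            for t in truth:
                if rng.random() < 0.8:
                    preds.append(
                        (BBox(t.x + rng.randint(-8, 8), t.y + rng.randint(-8, 8),
                              t.w, t.h), round(rng.random(), 3))
                    )
            for _ in range(rng.randint(0, 2)):
                preds.append(
                    (BBox(rng.randint(0, 500), 300, 30, 30), round(rng.random(), 3))
                )
            assert detection_metrics(preds, truth) == detection_metrics_oracle(
                preds, truth
            )
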