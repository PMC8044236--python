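"""Confusion counts, the printed metric formulas, ROC/AUC and reports."""

import json
import math

import numpy as np
import pytest

from woeqsar.evaluation import (
    ConfusionCounts, MetricsReport, accuracy, confusion, evaluate_predictions,
    f1, per_class_metrics, precision, recall, render_reports, roc_auc,
    round_half_up,
)


class TestConfusion:
    def test_perfect_and_inverted_two_row_panels(self):
        assert confusion([1, 0], [1, 0]) == ConfusionCounts(1, 1, 0, 0)
        assert confusion([1, 0], [0, 1]) == ConfusionCounts(0, 0, 1, 1)

    def test_matches_bruteforce_pair_counting(self, rng):
        t = rng.integers(0, 2, 100)
        p = rng.integers(0, 2, 100)
        c = confusion(t, p)
        ref = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for a, b in zip(t, p):
            key = ("t" if a == b else "f") + ("p" if b == 1 else "n")
            ref[key] += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (ref["tp"], ref["tn"],
                                            ref["fp"], ref["fn"])
        assert c.n == 100

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestFormulas:
    def test_f1_reproduces_published_sub_model_cell(self):
        # positive-class precision .650 / recall .481 prints as F1 .553
        assert round_half_up(f1(0.650, 0.481)) == 0.553

    def test_f1_reproduces_published_fusion_cell(self):
        # fused-model positive class: precision .802, recall 1 -> .890
        assert round_half_up(f1(0.802, 1.0)) == 0.890

    def test_f1_fixed_point_when_precision_equals_recall(self):
        for p in (0.1, 0.5, 0.937):
            assert f1(p, p) == pytest.approx(p)

    def test_accuracy_is_tp_tn_over_n(self):
        c = ConfusionCounts(tp=3, tn=5, fp=1, fn=1)
        assert accuracy(c) == 0.8
        assert precision(c) == 0.75
        assert recall(c) == 0.75

    def test_zero_denominators_are_undefined_not_zero(self):
        none_predicted_positive = ConfusionCounts(tp=0, tn=5, fp=0, fn=2)
        assert math.isnan(precision(none_predicted_positive))
        no_true_positives = ConfusionCounts(tp=0, tn=5, fp=2, fn=0)
        assert math.isnan(recall(no_true_positives))
        assert math.isnan(f1(float("nan"), 0.5))
        assert math.isnan(f1(0.0, 0.0))

    def test_round_half_up_at_the_boundary(self):
        assert round_half_up(0.8905, 3) == 0.891
        assert round_half_up(0.5535, 3) == 0.554
        assert round_half_up(-0.0025, 3) == -0.003


class TestPerClass:
    def test_perfect_predictions_score_one_in_both_classes(self, rng):
        y = rng.integers(0, 2, 50)
        m = per_class_metrics(y, y)
        for k in ("accuracy", "precision_pos", "recall_pos", "f1_pos",
                  "precision_neg", "recall_neg", "f1_neg"):
            assert m[k] == 1.0

    def test_all_positive_predictor_on_balanced_panel(self):
        y = np.array([0, 1] * 20)
        m = per_class_metrics(y, np.ones_like(y))
        assert m["recall_pos"] == 1.0
        assert m["recall_neg"] == 0.0
        assert m["accuracy"] == 0.5

    def test_label_swap_symmetry(self, rng):
        """Negative-class block equals the positive-class block computed
        after relabeling 0 <-> 1."""
        y = rng.integers(0, 2, 80)
        p = rng.integers(0, 2, 80)
        m = per_class_metrics(y, p)
        swapped = per_class_metrics(1 - y, 1 - p)
        assert m["precision_neg"] == swapped["precision_pos"]
        assert m["recall_neg"] == swapped["recall_pos"]
        assert m["accuracy"] == swapped["accuracy"]


class TestRocAuc:
    def test_scores_equal_to_labels_give_perfect_auc(self):
        y = np.array([0, 1, 1, 0, 1])
        auc, pts = roc_auc(y, y.astype(float))
        assert auc == 1.0
        assert len(pts) >= 2

    def test_constant_scores_give_half(self):
        y = np.array([0, 1] * 10)
        auc, _ = roc_auc(y, np.full(20, 0.4))
        assert auc == 0.5

    def test_matches_bruteforce_concordance_counting(self, rng):
        """AUC equals (concordant + 0.5*tied) / (pos*neg) pairs."""
        for _ in range(5):
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(30), 1)  # coarse grid forces ties
            auc, _ = roc_auc(y, s)
            pos = s[y == 1]
            neg = s[y == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(conc / (len(pos) * len(neg)))

    def test_single_class_is_undefined(self):
        auc, pts = roc_auc(np.ones(5, int), np.linspace(0, 1, 5))
        assert math.isnan(auc)
        assert len(pts) == 0

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0, 1], [0.5, 1.5])


class TestReports:
    @staticmethod
    def _fake_reports(rng):
        reports = []
        for algo in ("RF", "SVM", "BP"):
            for ep in ("Y1", "Y2", "Y3"):
                for split in ("train", "test"):
                    y = rng.integers(0, 2, 40)
                    p = rng.integers(0, 2, 40)
                    s = rng.random(40)
                    reports.append(evaluate_predictions(
                        y, p, s, algorithm=algo, target=ep, split=split))
            y = rng.integers(0, 2, 40)
            reports.append(evaluate_predictions(
                y, rng.integers(0, 2, 40), rng.random(40),
                algorithm=algo, target="fusion", split="test"))
        return reports

    def test_empty_metrics_give_schema_valid_tables(self, tmp_path):
        tables = render_reports([], tmp_path, plot_roc=False)
        assert set(tables) == {"accuracy_table", "submodel_table",
                               "fusion_table", "all_rows"}
        assert (tmp_path / "metrics.json").exists()

    def test_submodel_table_has_nine_rows(self, rng, tmp_path):
        tables = render_reports(self._fake_reports(rng), tmp_path,
                                plot_roc=False)
        assert len(tables["submodel_table"]) == 9   # 3 algorithms x 3 endpoints
        assert len(tables["fusion_table"]) == 3
        data = json.loads((tmp_path / "metrics.json").read_text())
        assert data["schema_version"] == 1
        assert len(data["rows"]) == len(tables["all_rows"])

    def test_report_row_recomputes_its_own_f1(self, rng):
        """Printed F1 must match 2pr/(p+r) of the row's own cells."""
        for rep in self._fake_reports(rng):
            row = rep.row()
            for cls in ("pos", "neg"):
                p, r = row[f"precision_{cls}"], row[f"recall_{cls}"]
                if not (math.isnan(p) or math.isnan(r) or p + r == 0):
                    expect = rep.metrics[f"precision_{cls}"], rep.metrics[f"recall_{cls}"]
                    assert row[f"f1_{cls}"] == round_half_up(f1(*expect))

    def test_json_round_trip(self, rng):
        rep = self._fake_reports(rng)[0]
        data = json.loads(rep.to_json())
        assert data["algorithm"] == rep.algorithm
        assert data["accuracy"] == rep.row()["accuracy"]
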