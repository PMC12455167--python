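"""Metric panel against independent oracles and closed-form identities.

The frozen 4-d.p. values for the (tp=9, fp=50, fn=2, tn=709) worked example
were derived by direct evaluation of the closed-form definitions before the
implementation existed; sklearn serves as a second, independent cross-check
on random tables.
"""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    cohen_kappa_score,
    f1_score,
    fbeta_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
)

from triscreen.metrics import (
    ConfusionMatrix,
    MetricWarning,
    agreement_metrics,
    class_metrics,
    confusion_from_verdicts,
    kappa_pabak_test,
    weighted_summary,
)


class TestConfusionFromVerdicts:
    def test_perfect_agreement_counts(self):
        gold = {f"r{i}": ("include" if i < 4 else "exclude") for i in range(10)}
        cm = confusion_from_verdicts(gold, gold)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (4, 0, 0, 6)

    def test_stated_screening_scenario_counts(self):
        # gold: 11 includes of 770; system predicts 59 includes, 9 correct
        gold, verdicts = {}, {}
        for i in range(770):
            rid = f"r{i:03d}"
            gold[rid] = "include" if i < 11 else "exclude"
            verdicts[rid] = "include" if (i < 9 or 11 <= i < 61) else "exclude"
        cm = confusion_from_verdicts(verdicts, gold)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (9, 50, 2, 709)

    def test_verdict_id_absent_from_gold_errors(self):
        with pytest.raises(ValueError, match="ghost"):
            confusion_from_verdicts({"ghost": "include"}, {"r1": "include"})

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion_from_verdicts(
                {"a": "include", "b": "maybe"},
                {"a": "include", "b": "exclude"},
            )

    def test_dataframe_inputs_accepted(self):
        verdicts = pd.DataFrame({"record_id": ["a", "b"], "final": ["include", "exclude"]})
        gold = pd.DataFrame({"record_id": ["a", "b"], "label": ["exclude", "exclude"]})
        cm = confusion_from_verdicts(verdicts, gold)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 1, 0, 1)


WORKED = ConfusionMatrix(tp=9, fp=50, fn=2, tn=709)


class TestClassMetrics:
    def test_worked_example_frozen_values(self):
        r = class_metrics(WORKED, beta=2)
        assert round(r.positive_precision, 4) == 0.1525
        assert round(r.positive_recall, 4) == 0.8182
        assert round(r.positive_f1, 4) == 0.2571
        assert round(r.f_beta, 4) == 0.4369
        assert round(r.balanced_accuracy, 4) == 0.8762
        assert round(r.mcc, 4) == 0.3356

    def test_worked_example_swapped_positive_class(self):
        r = class_metrics(WORKED.swap_positive(), beta=2)
        assert r.positive_precision == pytest.approx(709 / 711)
        assert r.positive_recall == pytest.approx(709 / 759)

    def test_perfect_matrix_all_ones(self):
        r = class_metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=7), beta=2)
        for value in r.as_dict().values():
            assert value == pytest.approx(1.0)

    def test_beta_one_equals_f1(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(0, 40, size=4)
            if tp + fp + fn + tn == 0 or tp + fn == 0:
                continue
            r = class_metrics(ConfusionMatrix(int(tp), int(fp), int(fn), int(tn)), beta=1)
            if r.positive_f1 is not None:
                assert r.f_beta == pytest.approx(r.positive_f1)

    def test_sklearn_cross_check_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 200))
            y_true = rng.integers(0, 2, size=n)
            y_pred = rng.integers(0, 2, size=n)
            if y_true.sum() in (0, n) or y_pred.sum() in (0, n):
                continue  # degenerate marginals follow documented conventions instead
            tp = int(np.sum((y_true == 1) & (y_pred == 1)))
            fp = int(np.sum((y_true == 0) & (y_pred == 1)))
            fn = int(np.sum((y_true == 1) & (y_pred == 0)))
            tn = int(np.sum((y_true == 0) & (y_pred == 0)))
            r = class_metrics(ConfusionMatrix(tp, fp, fn, tn), beta=2)
            assert r.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
            assert r.positive_precision == pytest.approx(
                precision_score(y_true, y_pred, zero_division=0)
            )
            assert r.positive_recall == pytest.approx(recall_score(y_true, y_pred))
            assert r.positive_f1 == pytest.approx(f1_score(y_true, y_pred))
            assert r.f_beta == pytest.approx(fbeta_score(y_true, y_pred, beta=2))
            assert r.balanced_accuracy == pytest.approx(
                balanced_accuracy_score(y_true, y_pred)
            )
            assert r.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)
            assert r.kappa == pytest.approx(cohen_kappa_score(y_true, y_pred))

    def test_zero_predicted_positives_precision_zero_with_warning(self):
        with pytest.warns(MetricWarning, match="precision"):
            r = class_metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=7))
        assert r.positive_precision == 0.0

    def test_zero_actual_positives_recall_missing(self):
        r = class_metrics(ConfusionMatrix(tp=0, fp=2, fn=0, tn=8))
        assert r.positive_recall is None
        assert r.positive_f1 is None
        assert r.balanced_accuracy is None

    def test_mcc_zero_factor_convention(self):
        r = class_metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
        assert r.mcc == 0.0


class TestAgreementMetrics:
    def test_worked_example_frozen_values(self):
        p_o, p_e, kappa, pabak = agreement_metrics(WORKED)
        assert round(p_o, 4) == 0.9325
        assert round(kappa, 4) == 0.2388
        assert round(pabak, 4) == 0.8649

    def test_symmetric_marginals_make_kappa_equal_pabak(self):
        # tp=40, fp=10, fn=10, tn=40: p_e = 0.5, so kappa = PABAK = 0.6
        p_o, p_e, kappa, pabak = agreement_metrics(ConfusionMatrix(40, 10, 10, 40))
        assert p_e == pytest.approx(0.5)
        assert kappa == pytest.approx(pabak) == pytest.approx(0.6)

    def test_perfect_agreement(self):
        _, _, kappa, pabak = agreement_metrics(ConfusionMatrix(3, 0, 0, 7))
        assert kappa == 1.0 and pabak == 1.0

    def test_pabak_is_two_accuracy_minus_one_everywhere(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 50, size=4))
            if tp + fp + fn + tn == 0:
                continue
            cm = ConfusionMatrix(tp, fp, fn, tn)
            p_o, _, _, pabak = agreement_metrics(cm)
            assert pabak == pytest.approx(2 * p_o - 1)

    def test_degenerate_pe_one_convention(self):
        # all records in one class, predicted the same way: p_e = 1
        _, p_e, kappa, _ = agreement_metrics(ConfusionMatrix(0, 0, 0, 10))
        assert p_e == 1.0 and kappa == 1.0
        _, p_e2, kappa2, _ = agreement_metrics(ConfusionMatrix(0, 10, 0, 0))
        assert p_e2 != 1.0 or kappa2 in (0.0, 1.0)

    def test_class_swap_leaves_symmetric_metrics_unchanged(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            tp, fp, fn, tn = (int(x) for x in rng.integers(1, 50, size=4))
            cm = ConfusionMatrix(tp, fp, fn, tn)
            a, b = class_metrics(cm, beta=2), class_metrics(cm.swap_positive(), beta=2)
            assert a.accuracy == pytest.approx(b.accuracy)
            assert a.mcc == pytest.approx(b.mcc)
            assert a.kappa == pytest.approx(b.kappa)
            assert a.pabak == pytest.approx(b.pabak)
            assert a.balanced_accuracy == pytest.approx(b.balanced_accuracy)
            assert a.positive_precision == pytest.approx(b.negative_precision)
            assert a.positive_recall == pytest.approx(b.negative_recall)


class TestWeightedSummary:
    def test_two_dataset_weighted_mean_and_pabak_linearity(self):
        per = [
            ({"accuracy": 0.9, "pabak": 2 * 0.9 - 1}, 100),
            ({"accuracy": 1.0, "pabak": 2 * 1.0 - 1}, 300),
        ]
        s = weighted_summary(per)
        assert s.weighted_mean["accuracy"] == pytest.approx(0.975)
        assert s.weighted_mean["pabak"] == pytest.approx(0.95)
        assert s.weighted_mean["pabak"] == pytest.approx(
            2 * s.weighted_mean["accuracy"] - 1
        )

    def test_pooled_accuracy_prints_as_reported(self):
        s = weighted_summary([({"accuracy": 26735 / 27982}, 27982)])
        assert round(100 * s.pooled_accuracy, 2) == 95.54
        assert round(s.pooled_accuracy, 2) == 0.96

    def test_single_dataset_sd_zero_mean_equals_value(self):
        s = weighted_summary([({"accuracy": 0.87}, 500)])
        assert s.weighted_mean["accuracy"] == pytest.approx(0.87)
        assert s.sd["accuracy"] == 0.0
        assert s.value_range["accuracy"] == (0.87, 0.87)

    def test_weighted_mean_within_range(self):
        rng = np.random.default_rng(3)
        values = rng.random(9)
        weights = rng.integers(100, 9000, size=9)
        s = weighted_summary(
            [({"m": float(v)}, int(w)) for v, w in zip(values, weights)]
        )
        lo, hi = s.value_range["m"]
        assert lo <= s.weighted_mean["m"] <= hi

    def test_missing_metric_values_skipped(self):
        s = weighted_summary([({"recall": None}, 10), ({"recall": 0.8}, 30)])
        assert s.weighted_mean["recall"] == pytest.approx(0.8)


class TestKappaPabakTest:
    def test_identical_vectors_degenerate_flagged(self):
        res = kappa_pabak_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert res.degenerate and res.statistic is None and res.p_value is None

    def test_paired_t_against_textbook_formula(self):
        kappas = [0.2, 0.3, 0.4, 0.25]
        pabaks = [0.8, 0.85, 0.9, 0.82]
        res = kappa_pabak_test(kappas, pabaks)
        # independent textbook computation of the paired t statistic
        diffs = [k - p for k, p in zip(kappas, pabaks)]
        n = len(diffs)
        dbar = sum(diffs) / n
        sd = math.sqrt(sum((d - dbar) ** 2 for d in diffs) / (n - 1))
        t_oracle = dbar / (sd / math.sqrt(n))
        assert res.method == "paired t"
        assert res.df == n - 1
        assert res.statistic == pytest.approx(t_oracle)
        assert res.p_value is not None and res.p_value < 0.05
        assert res.mean_kappa == pytest.approx(0.2875)
        assert res.mean_pabak == pytest.approx(0.8425)

    def test_nine_dataset_shape_matches_study_design(self):
        # 9 paired values -> t with df = 8 when differences are normal
        rng = np.random.default_rng(1)
        kappas = 0.25 + 0.05 * rng.standard_normal(9)
        pabaks = 0.87 + 0.03 * rng.standard_normal(9)
        res = kappa_pabak_test(kappas, pabaks)
        if res.method == "paired t":
            assert res.df == 8
        assert res.mean_kappa < res.mean_pabak

    def test_skewed_differences_fall_back_to_wilcoxon(self):
        rng = np.random.default_rng(2)
        pabaks = np.full(20, 0.9)
        kappas = pabaks - rng.exponential(0.2, size=20) ** 2  # heavily skewed diffs
        res = kappa_pabak_test(kappas, pabaks)
        assert res.normality_p is not None
        if res.normality_p < 0.05:
            assert res.method == "wilcoxon signed rank"
            assert res.df is None

    def test_length_mismatch_and_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            kappa_pabak_test([0.1, 0.2], [0.3, 0.4, 0.5])
        with pytest.raises(ValueError):
            kappa_pabak_test([0.1, 0.2], [0.3, 0.4])
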