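import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

from pgxmark import (
    ConfusionMatrix,
    MetricSet,
    compare_drug,
    confusion,
    f_score,
    mcc,
    metric_set,
    precision_recall,
    summarize_cohort,
)
from pgxmark.evaluation import (
    comparisons_table,
    export_reports,
    spearman_two_tailed,
)


def _labels_from_counts(cm: ConfusionMatrix):
    y_true = [True] * cm.tp + [False] * cm.tn + [False] * cm.fp + [True] * cm.fn
    y_pred = [True] * cm.tp + [False] * cm.tn + [True] * cm.fp + [False] * cm.fn
    return np.array(y_true), np.array(y_pred)


class TestConfusion:
    def test_enumerated_example(self):
        cm = confusion([True, True, False, False], [True, False, True, False])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        y = np.array([True, False, True])
        cm = confusion(y, y)
        assert cm.fp == cm.fn == 0

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        t = rng.random(1000) < 0.5
        p = rng.random(1000) < 0.5
        cm = confusion(t, p)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for a, b in zip(t, p):
            tally["tp" if a and b else "tn" if not a and not b else "fp" if b else "fn"] += 1
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (
            tally["tp"], tally["tn"], tally["fp"], tally["fn"]
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([True], [True, False])


class TestMcc:
    def test_perfect_and_antiperfect(self):
        assert mcc(ConfusionMatrix(2, 2, 0, 0)) == 1.0
        assert mcc(ConfusionMatrix(0, 0, 2, 2)) == -1.0

    def test_formula_oracle(self):
        cm = ConfusionMatrix(tp=3, tn=2, fp=1, fn=4)
        expected = (3 * 2 - 1 * 4) / math.sqrt((3 + 4) * (4 + 2) * (2 + 1) * (1 + 3))
        assert mcc(cm) == pytest.approx(expected, abs=1e-15)

    def test_agrees_with_sklearn_on_label_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            cm = ConfusionMatrix(*rng.integers(0, 20, size=4))
            if cm.total == 0:
                continue
            t, p = _labels_from_counts(cm)
            assert mcc(cm) == pytest.approx(matthews_corrcoef(t, p), abs=1e-12)

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionMatrix(5, 0, 0, 0)) == 0.0  # no negatives at all
        assert mcc(ConfusionMatrix(0, 5, 0, 0)) == 0.0

    def test_no_prediction_flag_forces_zero(self):
        assert mcc(ConfusionMatrix(3, 2, 1, 4), no_prediction=True) == 0.0


class TestPrecisionRecallF1:
    def test_printed_example(self):
        """High-precision/low-recall marker: PR=0.75, RC=0.05, F1=0.09375."""
        pr, rc = precision_recall(ConfusionMatrix(tp=3, tn=100, fp=1, fn=57))
        assert pr == 0.75 and rc == pytest.approx(0.05)
        assert f_score(pr, rc) == pytest.approx(0.09375)

    def test_zero_conventions(self):
        pr, rc = precision_recall(ConfusionMatrix(0, 10, 0, 5))
        assert pr == 0.0
        pr, rc = precision_recall(ConfusionMatrix(0, 10, 3, 0))
        assert rc == 0.0
        assert f_score(0.0, 0.0) == 0.0

    def test_perfect_prediction(self):
        pr, rc = precision_recall(ConfusionMatrix(5, 5, 0, 0))
        assert pr == rc == 1.0 and f_score(pr, rc) == 1.0

    def test_no_prediction_zeroes_precision(self):
        pr, _ = precision_recall(ConfusionMatrix(0, 5, 0, 5), no_prediction=True)
        assert pr == 0.0

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_f1_between_min_and_max(self, pr, rc):
        f1 = f_score(pr, rc)
        assert 0 <= f1 <= 1
        if pr > 0 and rc > 0:
            assert min(pr, rc) - 1e-12 <= f1 <= max(pr, rc) + 1e-12
        assert (f1 == 1.0) == (pr == 1.0 and rc == 1.0)


class TestSpearman:
    def test_monotone_small_sample_exact_p(self):
        rho, p = spearman_two_tailed([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(5))  # identity + reversal

    def test_constant_input_not_computable(self):
        assert spearman_two_tailed([1, 1, 1], [1, 2, 3]) == (None, None)

    def test_large_sample_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p = spearman_two_tailed(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


def _comparison(drug_id, s_test, m_test, drug_class="targeted", imbalance=0, size=10,
                s_train=None, m_train=None, m_cv=None):
    metrics = {
        ("single_gene", "test"): s_test,
        ("multi_gene", "test"): m_test,
        ("single_gene", "train"): s_train or s_test,
        ("multi_gene", "train"): m_train or m_test,
        ("multi_gene", "cv"): m_cv or m_test,
    }
    from pgxmark.evaluation import DrugComparison

    return DrugComparison(
        drug_id=drug_id, drug_class=drug_class, metrics=metrics,
        test_imbalance=imbalance, test_size=size,
    )


def _ms(mcc_=0.0, pr=0.0, rc=0.0, f1=None, no_prediction=False):
    return MetricSet(
        mcc=mcc_, precision=pr, recall=rc,
        f1=f_score(pr, rc) if f1 is None else f1, no_prediction=no_prediction,
    )


class TestCompareAndSummarize:
    def test_identical_metrics_are_ties(self):
        comps = [
            _comparison("d1", _ms(0.3, 0.5, 0.5), _ms(0.3, 0.5, 0.5)),
            _comparison("d2", _ms(0.1, 0.2, 0.2), _ms(0.1, 0.2, 0.2)),
        ]
        summary = summarize_cohort(comps)
        for metric in ("mcc", "precision", "recall", "f1"):
            assert summary.win_counts[metric]["ties"] == 2

    def test_recall_win_count(self):
        comps = [
            _comparison("d1", _ms(0.2, 0.6, 0.1), _ms(0.2, 0.5, 0.6)),
            _comparison("d2", _ms(0.1, 0.4, 0.2), _ms(0.3, 0.5, 0.7)),
        ]
        summary = summarize_cohort(comps)
        assert summary.win_counts["recall"]["multi_wins"] == 2

    def test_win_counts_antisymmetric(self):
        rng = np.random.default_rng(4)
        comps, swapped = [], []
        for i in range(20):
            s, m = _ms(*rng.random(3)), _ms(*rng.random(3))
            comps.append(_comparison(f"d{i}", s, m))
            swapped.append(_comparison(f"d{i}", m, s))
        a = summarize_cohort(comps).win_counts
        b = summarize_cohort(swapped).win_counts
        for metric in a:
            assert a[metric]["multi_wins"] == b[metric]["single_wins"]
            assert a[metric]["ties"] == b[metric]["ties"]

    def test_sign_table_partitions_cohort(self):
        rng = np.random.default_rng(5)
        comps = [
            _comparison(f"d{i}", _ms(rng.uniform(-1, 1)), _ms(rng.uniform(-1, 1)))
            for i in range(30)
        ]
        summary = summarize_cohort(comps)
        assert sum(summary.sign_table.values()) == 30

    def test_zero_mcc_binned_nonpositive_and_counted(self):
        comps = [
            _comparison("d1", _ms(0.0), _ms(0.5)),
            _comparison("d2", _ms(0.2), _ms(0.1)),
        ]
        summary = summarize_cohort(comps)
        assert summary.sign_table["rf_pos_single_nonpos"] == 1
        assert summary.zero_mcc_ties["single_gene"] == 1

    def test_all_equal_mcc_flags_spearman_not_computable(self):
        comps = [_comparison(f"d{i}", _ms(0.1), _ms(0.2), size=10 + i) for i in range(5)]
        summary = summarize_cohort(comps)
        assert summary.spearman_imbalance == (None, None)

    def test_planted_monotone_size_effect_detected(self):
        """Test MCC rising with test size gives a positive, significant rho."""
        rng = np.random.default_rng(6)
        comps = []
        for i in range(40):
            size = 20 + i * 5
            m = _ms(mcc_=size / 300 + rng.normal(0, 0.01))
            comps.append(_comparison(f"d{i}", _ms(0.0), m, size=size, imbalance=0))
        summary = summarize_cohort(comps)
        rho, p = summary.spearman_test_size
        assert rho > 0.9 and p < 1e-6

    def test_balanced_test_set_has_zero_imbalance(self):
        comp = compare_drug(
            "d", {"test": _ms()}, {"test": _ms()}, [True, False, True, False]
        )
        assert comp.test_imbalance == 0 and comp.test_size == 4

    def test_no_prediction_marker_recorded_not_dropped(self):
        comps = [
            _comparison("d1", _ms(no_prediction=True), _ms(0.4)),
            _comparison("d2", _ms(0.1), _ms(0.2)),
        ]
        summary = summarize_cohort(comps)
        assert summary.no_prediction_drugs == ["d1"]
        assert summary.n_drugs == 2

    def test_too_few_comparisons_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([_comparison("d1", _ms(), _ms())])


class TestExport:
    def test_round_trip_full_precision(self, tmp_path):
        rng = np.random.default_rng(7)
        comps = [
            _comparison(f"d{i}", _ms(*rng.random(3)), _ms(*rng.random(3)))
            for i in range(6)
        ]
        summary = summarize_cohort(comps)
        paths = export_reports(summary, comps, tmp_path)
        table = pd.read_csv(paths["per_drug_metrics"], float_precision="round_trip")
        expected = comparisons_table(comps)
        for col in ("mcc", "precision", "recall", "f1"):
            assert (table[col].to_numpy() == expected[col].to_numpy()).all()
        assert len(table) == len(expected)

    def test_row_count_per_model_dataset(self, tmp_path):
        comps = [_comparison(f"d{i}", _ms(0.1), _ms(0.2)) for i in range(4)]
        table = comparisons_table(comps)
        assert len(table) == 4 * 5  # 2 single + 3 multi slots per drug

    def test_empty_export_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_reports(None, [], tmp_path)


def test_random_predictor_calibration():
    """Mean MCC of a coin-flip predictor on balanced labels is near zero."""
    rng = np.random.default_rng(8)
    vals = []
    for _ in range(2000):
        t = np.repeat([True, False], 20)
        p = rng.random(40) < 0.5
        vals.append(mcc(confusion(t, p)))
    assert abs(np.mean(vals)) < 0.02
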