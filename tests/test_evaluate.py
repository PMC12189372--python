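import numpy as np
import pytest
from sklearn import metrics as skm

from plantrbp.evaluate import (
    ConfusionCounts,
    PairedComparison,
    UndefinedMetricError,
    aggregate_folds,
    compare_feature_sets,
    confusion,
    cross_validate,
    evaluate_predictions,
    metrics,
)
from plantrbp.seqio import LabeledSequence


def test_confusion_hand_counts():
    c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
    assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 1)
    c = confusion([1] * 6 + [0] * 4, [1] * 6 + [0] * 4)
    assert (c.TP, c.TN, c.FP, c.FN) == (6, 4, 0, 0)
    c = confusion([1, 0], [1, 1])
    assert (c.TP, c.FP, c.TN, c.FN) == (1, 1, 0, 0)


def test_confusion_rejects_non_binary():
    with pytest.raises(ValueError, match="binary"):
        confusion([1, 2], [1, 0])


def test_metric_formulas_on_worked_example():
    m = metrics(ConfusionCounts(TP=50, TN=40, FP=10, FN=0))
    assert m.ACC == pytest.approx(90.0)
    assert m.SN == pytest.approx(100.0)
    assert m.SP == pytest.approx(80.0)
    assert m.Precision == pytest.approx(83.33, abs=0.01)
    assert m.F1 == pytest.approx(90.91, abs=0.01)
    assert m.MCC == pytest.approx(100 * 2000 / np.sqrt(60 * 50 * 50 * 40),
                                  abs=1e-9)


def test_perfect_and_chance_classifiers():
    perfect = metrics(ConfusionCounts(5, 5, 0, 0))
    assert perfect.ACC == 100.0 and perfect.MCC == 100.0
    chance = metrics(ConfusionCounts(25, 25, 25, 25))
    assert chance.MCC == 0.0


def test_zero_denominators_are_named_not_zeroed():
    m = metrics(ConfusionCounts(TP=0, TN=10, FP=0, FN=5))
    assert m.Precision is None
    assert "TP+FP" in m.undefined["Precision"]
    assert m.MCC is None and "TP+FP" in m.undefined["MCC"]
    with pytest.raises(UndefinedMetricError):
        metrics(ConfusionCounts(0, 0, 0, 0))


def test_metrics_match_sklearn_oracle_on_random_vectors(rng):
    """Formula implementation vs scikit-learn on 1000 random cases."""
    for _ in range(1000):
        n = int(rng.integers(4, 40))
        y = rng.integers(0, 2, n)
        yhat = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2 or len(np.unique(yhat)) < 2:
            continue
        m = metrics(confusion(y, yhat))
        assert m.ACC == pytest.approx(100 * skm.accuracy_score(y, yhat))
        assert m.SN == pytest.approx(100 * skm.recall_score(y, yhat))
        assert m.Precision == pytest.approx(
            100 * skm.precision_score(y, yhat), abs=1e-10)
        assert m.F1 == pytest.approx(100 * skm.f1_score(y, yhat), abs=1e-10)
        assert m.MCC == pytest.approx(
            100 * skm.matthews_corrcoef(y, yhat), abs=1e-10)


def test_weighted_averaging_matches_sklearn(rng):
    y = rng.integers(0, 2, 200)
    yhat = rng.integers(0, 2, 200)
    m = metrics(confusion(y, yhat), averaging="weighted")
    assert m.F1 == pytest.approx(
        100 * skm.f1_score(y, yhat, average="weighted"), abs=1e-10)
    assert m.Precision == pytest.approx(
        100 * skm.precision_score(y, yhat, average="weighted"), abs=1e-10)


def test_auc_depends_only_on_score_ranks(rng):
    y = rng.integers(0, 2, 100)
    scores = rng.random(100)
    a = evaluate_predictions(y, scores).AUC
    b = evaluate_predictions(y, 1 / (1 + np.exp(-5 * scores))).AUC
    assert a == pytest.approx(b, abs=1e-10)


def test_fold_aggregation_uses_population_std():
    folds = [96.10, 97.30, 97.60, 97.39, 97.60]
    mean, std = aggregate_folds(folds, ddof=0)
    assert round(mean, 2) == 97.20
    assert round(std, 2) == 0.56
    _, sample_std = aggregate_folds(folds, ddof=1)
    assert round(sample_std, 2) != 0.56  # the flag matters


class _ThresholdPipeline:
    """Scores by mean composition of residue 'R'; records what it saw."""

    seen_test_ids: list = []

    def fit(self, sequences):
        self.train_ids = {s.id for s in sequences}

    def predict_proba(self, sequences):
        type(self).seen_test_ids.extend(s.id for s in sequences)
        return np.array([s.residues.count("R") / len(s.residues) + 0.25
                         for s in sequences]).clip(0, 1)


def _toy_sequences(n=30):
    half = n // 2
    seqs = [LabeledSequence(f"p{i}", "RRRRRAAAAA", 1) for i in range(half)]
    seqs += [LabeledSequence(f"n{i}", "AAAAAAAAAA", 0) for i in range(half)]
    return seqs


def test_cross_validation_partitions_each_sample_once():
    seqs = _toy_sequences(30)
    _ThresholdPipeline.seen_test_ids = []
    summary = cross_validate(_ThresholdPipeline, seqs, n_folds=5, seed=0)
    assert summary.n_folds == 5
    assert sorted(_ThresholdPipeline.seen_test_ids) == sorted(s.id for s in seqs)
    assert len(summary.folds) == 5
    assert summary.mean("ACC") == 100.0


def test_cross_validation_is_deterministic():
    seqs = _toy_sequences(20)
    s1 = cross_validate(_ThresholdPipeline, seqs, n_folds=4, seed=3)
    s2 = cross_validate(_ThresholdPipeline, seqs, n_folds=4, seed=3)
    assert s1.per_fold("ACC") == s2.per_fold("ACC")


def test_summary_table_formats_mean_and_std():
    seqs = _toy_sequences(30)
    summary = cross_validate(_ThresholdPipeline, seqs, n_folds=5, seed=0)
    table = summary.table()
    assert table.iloc[-1]["fold"] == "Average"
    assert table.iloc[-1]["ACC"] == "100.00 ± 0.00"


def test_paired_comparison_detects_shift(rng):
    a = 70 + rng.normal(0, 1.0, size=10)
    b = a + 5 + rng.normal(0, 0.5, size=10)
    res = compare_feature_sets(a, b)
    assert isinstance(res, PairedComparison)
    assert res.p_value < 0.05
    assert 0 < res.shapiro_p < 1


def test_paired_comparison_overlapping_sets_in_range(rng):
    a = 70 + rng.normal(0, 2, size=10)
    b = rng.permutation(a) + rng.normal(0, 0.01, size=10)
    res = compare_feature_sets(a, b)
    assert 0 < res.p_value < 1


def test_paired_comparison_identical_vectors_undefined(rng):
    a = rng.normal(size=8)
    with pytest.raises(UndefinedMetricError):
        compare_feature_sets(a, a.copy())
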