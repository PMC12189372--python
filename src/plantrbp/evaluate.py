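"""Confusion-matrix metrics, ROC/AUC, cross-validation, and paired tests.

All rate metrics are reported as percentages:

    ACC = (TP + TN) / (TP + TN + FP + FN) * 100
    SN  = TP / (TP + FN) * 100          (sensitivity, recall)
    SP  = TN / (TN + FP) * 100          (specificity)
    Precision = TP / (TP + FP) * 100
    F1  = 2*TP / (2*TP + FP + FN) * 100
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) * 100

Zero-denominator cases are reported as explicitly undefined with the zero
term named, never silently as 0.  Fold summaries use the population
(ddof = 0) standard deviation by default; sample std is available via a
flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

METRIC_NAMES = ("ACC", "AUC", "MCC", "F1", "SN", "SP", "Precision")


class UndefinedMetricError(ValueError):
    """Raised when a requested statistic has no defined value."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally the four confusion cells from binary label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, v in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass
class MetricSet:
    """Percent-scale metrics; ``undefined`` names any zero-denominator term."""

    ACC: float | None = None
    AUC: float | None = None
    MCC: float | None = None
    F1: float | None = None
    SN: float | None = None
    SP: float | None = None
    Precision: float | None = None
    undefined: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: float, den: float, metric: str, zero_term: str,
           undefined: dict[str, str]) -> float | None:
    if den == 0:
        undefined[metric] = f"undefined: {zero_term} = 0"
        return None
    return 100.0 * num / den


def metrics(
    counts: ConfusionCounts,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
    averaging: str = "binary",
) -> MetricSet:
    """Compute the metric set from confusion counts (plus AUC from scores).

    ``averaging="weighted"`` replaces F1 and Precision with support-weighted
    per-class averages (the convention used for independent-set reporting
    on balanced data); ``"binary"`` is the positive-class definition.
    """
    if counts.total == 0:
        raise UndefinedMetricError("no evaluated samples")
    if averaging not in ("binary", "weighted"):
        raise ValueError("averaging must be 'binary' or 'weighted'")
    TP, TN, FP, FN = counts.TP, counts.TN, counts.FP, counts.FN
    und: dict[str, str] = {}
    out = MetricSet(undefined=und)
    out.ACC = 100.0 * (TP + TN) / counts.total
    out.SN = _ratio(TP, TP + FN, "SN", "TP+FN", und)
    out.SP = _ratio(TN, TN + FP, "SP", "TN+FP", und)
    if averaging == "binary":
        out.Precision = _ratio(TP, TP + FP, "Precision", "TP+FP", und)
        out.F1 = _ratio(2 * TP, 2 * TP + FP + FN, "F1", "2TP+FP+FN", und)
    else:
        n1, n0 = TP + FN, TN + FP
        p1 = TP / (TP + FP) if TP + FP else None
        p0 = TN / (TN + FN) if TN + FN else None
        f1 = 2 * TP / (2 * TP + FP + FN) if 2 * TP + FP + FN else None
        f0 = 2 * TN / (2 * TN + FN + FP) if 2 * TN + FN + FP else None
        if None in (p1, p0) or n1 + n0 == 0:
            und["Precision"] = "undefined: a per-class precision denominator = 0"
        else:
            out.Precision = 100.0 * (n1 * p1 + n0 * p0) / (n1 + n0)
        if None in (f1, f0) or n1 + n0 == 0:
            und["F1"] = "undefined: a per-class F1 denominator = 0"
        else:
            out.F1 = 100.0 * (n1 * f1 + n0 * f0) / (n1 + n0)
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    if denom == 0:
        zero = [t for t, v in (("TP+FP", TP + FP), ("TP+FN", TP + FN),
                               ("TN+FP", TN + FP), ("TN+FN", TN + FN)) if v == 0]
        und["MCC"] = f"undefined: {'+'.join(zero)} = 0"
    else:
        out.MCC = 100.0 * (TP * TN - FP * FN) / math.sqrt(denom)
    if scores is not None:
        if y_true is None:
            raise ValueError("y_true required alongside scores for AUC")
        if len(np.unique(y_true)) < 2:
            und["AUC"] = "undefined: single-class y_true"
        else:
            out.AUC = 100.0 * float(roc_auc_score(y_true, scores))
    return out


def evaluate_predictions(
    y_true, scores, threshold: float = 0.5, averaging: str = "binary"
) -> MetricSet:
    """Metric set from continuous scores at a decision threshold."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    return metrics(confusion(y_true, y_pred), scores=scores, y_true=y_true,
                   averaging=averaging)


def roc_points(y_true, scores) -> pd.DataFrame:
    """ROC curve points (FPR, TPR, threshold) for CSV export."""
    fpr, tpr, thr = roc_curve(y_true, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class CVSummary:
    """Per-fold metric sets with mean ± std aggregation."""

    folds: list[MetricSet]
    n_folds: int
    seed: int
    ddof: int = 0

    def _values(self, name: str) -> list[float]:
        vals = [getattr(f, name) for f in self.folds]
        if any(v is None for v in vals):
            raise UndefinedMetricError(
                f"{name} undefined in some folds: "
                f"{[f.undefined.get(name) for f in self.folds]}"
            )
        return vals

    def mean(self, name: str) -> float:
        return float(np.mean(self._values(name)))

    def std(self, name: str) -> float:
        return float(np.std(self._values(name), ddof=self.ddof))

    def per_fold(self, name: str) -> list[float]:
        return self._values(name)

    def table(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.folds, start=1):
            rows.append({"fold": f"Fold {i}", **f.as_dict()})
        avg = {"fold": "Average"}
        for name in METRIC_NAMES:
            try:
                avg[name] = f"{self.mean(name):.2f} ± {self.std(name):.2f}"
            except UndefinedMetricError:
                avg[name] = "undefined"
        frame = pd.DataFrame(rows)
        frame = pd.concat([frame, pd.DataFrame([avg])], ignore_index=True)
        return frame


def aggregate_folds(
    values: Sequence[float], ddof: int = 0
) -> tuple[float, float]:
    """Mean and std of per-fold values under the chosen ddof convention."""
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=ddof))


def cross_validate(
    pipeline_factory: Callable[[], object],
    sequences: Sequence,
    n_folds: int = 5,
    seed: int = 0,
    averaging: str = "binary",
) -> CVSummary:
    """Stratified k-fold cross-validation of an end-to-end pipeline.

    ``pipeline_factory`` returns a fresh object with ``fit(sequences)``
    and ``predict_proba(sequences) -> scores``; the entire pipeline —
    stacking, selection, deep-model training — is refit on each fold's
    training portion only, so no test row influences any fitted component.
    """
    labels = np.asarray([s.label for s in sequences], dtype=int)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds: list[MetricSet] = []
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        train = [sequences[i] for i in train_idx]
        test = [sequences[i] for i in test_idx]
        pipeline = pipeline_factory()
        pipeline.fit(train)
        scores = np.asarray(pipeline.predict_proba(test), dtype=float)
        folds.append(evaluate_predictions(labels[test_idx], scores,
                                          averaging=averaging))
    return CVSummary(folds=folds, n_folds=n_folds, seed=seed)


@dataclass(frozen=True)
class PairedComparison:
    """One-tailed paired t-test (alternative: b > a) plus normality check."""

    t_statistic: float
    p_value: float
    shapiro_p: float
    n: int


def compare_feature_sets(
    per_fold_a: Sequence[float], per_fold_b: Sequence[float]
) -> PairedComparison:
    """Test whether feature set b outperforms a across paired folds.

    The Shapiro–Wilk statistic is computed on the paired differences; the
    t-test is one-tailed with alternative "b > a".  Identical vectors (zero
    difference variance) make both tests undefined.
    """
    a = np.asarray(per_fold_a, dtype=float)
    b = np.asarray(per_fold_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length paired fold metrics with n >= 3")
    diff = b - a
    if np.allclose(diff.std(), 0.0):
        raise UndefinedMetricError("zero variance in paired differences")
    shapiro_p = float(stats.shapiro(diff).pvalue)
    res = stats.ttest_rel(b, a, alternative="greater")
    return PairedComparison(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        shapiro_p=shapiro_p,
        n=int(a.size),
    )
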