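"""Base learners and leakage-safe stacked prediction columns.

Four learners feed the default ensemble — an RBF-kernel SVM, logistic
regression (LR), linear discriminant analysis (LDA), and LightGBM — and
their positive-class scores become extra feature columns named
``<NAME>_Pred_Result``.  The wider candidate pool spans eleven methods so
the correlation-pruning stage has something to prune.

Prediction columns for the training set are produced out-of-fold: the
score for row i always comes from a model whose training rows exclude i.
Unseen data are scored by models refit on the full training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

#: Learner names recognised by :func:`make_learner`.
LEARNER_NAMES = ("SVM", "LR", "LDA", "LightGBM", "XGB", "RF", "GBDT",
                 "KNN", "DT", "NB", "BG")

#: Learners whose inputs are standardized to zero mean / unit variance
#: (fit on training folds only); tree ensembles consume raw frequencies.
_NEEDS_SCALING = frozenset({"SVM", "LR", "LDA", "KNN"})


@dataclass(frozen=True)
class BaseLearnerSpec:
    """Name + hyperparameters of one base learner."""

    name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    @property
    def needs_scaling(self) -> bool:
        return self.name in _NEEDS_SCALING

    @property
    def column_name(self) -> str:
        return f"{self.name}_Pred_Result"


def default_specs() -> list[BaseLearnerSpec]:
    """The four learners of the final ensemble: SVM, LR, LDA, LightGBM."""
    return [BaseLearnerSpec(n) for n in ("SVM", "LR", "LDA", "LightGBM")]


def all_specs() -> list[BaseLearnerSpec]:
    """All eleven candidate learners for the selection stage."""
    return [BaseLearnerSpec(n) for n in LEARNER_NAMES]


class PlattScaledSVC(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM with a logistic (Platt) calibration of its margin.

    The SVC is fit once and a one-dimensional logistic regression maps its
    decision values to [0, 1].  Calibrating on the training margins keeps
    cost at a single SVC fit; out-of-fold stacking already shields the
    meta-level from in-sample optimism.
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "scale",
                 random_state: int | None = None):
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def fit(self, X, y):
        self.svc_ = SVC(kernel="rbf", C=self.C, gamma=self.gamma,
                        random_state=self.random_state)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        margins = self.svc_.decision_function(X).reshape(-1, 1)
        self.platt_ = LogisticRegression(C=1e6)
        self.platt_.fit(margins, y)
        return self

    def decision_function(self, X):
        return self.svc_.decision_function(X)

    def predict_proba(self, X):
        margins = self.svc_.decision_function(X).reshape(-1, 1)
        return self.platt_.predict_proba(margins)

    def predict(self, X):
        return self.svc_.predict(X)


def make_learner(spec: BaseLearnerSpec, seed: int = 0):
    """Build an unfitted classifier exposing fit / predict_proba.

    Scores from ``predict_proba`` are positive-class probabilities in
    [0, 1].  Learners that benefit from standardized inputs are wrapped in
    a scaling pipeline whose statistics are fit on the training rows only.
    """
    hp = dict(spec.hyperparameters)
    if spec.name == "SVM":
        est = PlattScaledSVC(random_state=seed, **hp)
    elif spec.name == "LR":
        est = LogisticRegression(max_iter=2000, random_state=seed, **hp)
    elif spec.name == "LDA":
        est = LinearDiscriminantAnalysis(**hp)
    elif spec.name == "LightGBM":
        from lightgbm import LGBMClassifier

        est = LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **hp)
    elif spec.name == "XGB":
        from xgboost import XGBClassifier

        est = XGBClassifier(random_state=seed, n_jobs=1,
                            use_label_encoder=False, eval_metric="logloss", **hp)
    elif spec.name == "RF":
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    elif spec.name == "GBDT":
        est = GradientBoostingClassifier(random_state=seed, **hp)
    elif spec.name == "KNN":
        est = KNeighborsClassifier(**hp)
    elif spec.name == "DT":
        est = DecisionTreeClassifier(random_state=seed, **hp)
    elif spec.name == "NB":
        est = GaussianNB(**hp)
    elif spec.name == "BG":
        est = BaggingClassifier(random_state=seed, n_jobs=1, **hp)
    else:
        raise ValueError(
            f"unknown learner {spec.name!r}; valid names: {LEARNER_NAMES}"
        )
    if spec.needs_scaling:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def _positive_proba(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    pos = int(np.flatnonzero(model.classes_ == 1)[0]) if hasattr(model, "classes_") \
        else 1
    if isinstance(model, Pipeline):
        pos = int(np.flatnonzero(model[-1].classes_ == 1)[0])
    return proba[:, pos]


def _check_folds(y: np.ndarray, n_folds: int) -> None:
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; stacking needs both")
    if counts.min() < n_folds:
        raise ValueError(
            f"minority class has {counts.min()} members < n_folds={n_folds}; "
            "reduce n_folds or change the stratification seed"
        )


def oof_predict(
    spec: BaseLearnerSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    folds: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Out-of-fold positive-class scores for one learner.

    Returns ``(column, auc, fold_assignment)``.  Folds are stratified and
    shuffled from ``seed``, so identical inputs give identical columns; a
    precomputed row -> fold assignment can be supplied instead to pin the
    partition across calls.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; stacking needs both")
    if folds is None:
        _check_folds(y, n_folds)
        fold_of = np.empty(len(y), dtype=int)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for fold, (_, test_idx) in enumerate(skf.split(X, y)):
            fold_of[test_idx] = fold
    else:
        fold_of = np.asarray(folds, dtype=int)
        if fold_of.shape != y.shape:
            raise ValueError("fold assignment must have one entry per row")
    column = np.empty(len(y))
    for fold in np.unique(fold_of):
        test = fold_of == fold
        if len(np.unique(y[~test])) < 2:
            raise ValueError(
                f"training portion for fold {fold} has a single class; "
                "use stratified folds or another seed"
            )
        model = make_learner(spec, seed=seed)
        model.fit(X[~test], y[~test])
        column[test] = _positive_proba(model, X[test])
    auc = float(roc_auc_score(y, column))
    return column, auc, fold_of


@dataclass
class StackingResult:
    """Out-of-fold prediction columns plus full-data models for scoring."""

    columns: pd.DataFrame
    fold_assignment: np.ndarray
    per_learner_auc: dict[str, float]
    fitted_full_models: dict[str, object]
    specs: list[BaseLearnerSpec]
    seed: int
    n_folds: int

    def predict_columns(self, X_new: np.ndarray) -> pd.DataFrame:
        """Score unseen rows with the full-training-set models."""
        X_new = np.asarray(X_new, dtype=float)
        return pd.DataFrame(
            {name: _positive_proba(m, X_new)
             for name, m in self.fitted_full_models.items()}
        )

    def save(self, out_dir: str | Path, ids: Sequence[str] | None = None) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table = self.columns.copy()
        table.insert(0, "fold", self.fold_assignment)
        if ids is not None:
            table.insert(0, "id", list(ids))
        table.to_csv(out_dir / "stacking_columns.csv", index=False)
        sidecar = {
            "per_learner_auc": self.per_learner_auc,
            "specs": [{"name": s.name, "hyperparameters": dict(s.hyperparameters)}
                      for s in self.specs],
            "seed": self.seed,
            "n_folds": self.n_folds,
        }
        (out_dir / "stacking_meta.json").write_text(json.dumps(sidecar, indent=2))


def build_stack(
    X: np.ndarray,
    y: np.ndarray,
    specs: Sequence[BaseLearnerSpec] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    oof: bool = True,
) -> StackingResult:
    """Build one prediction column per learner plus full-data models.

    With ``oof=True`` (default) training-set columns are leakage-safe
    out-of-fold scores; ``oof=False`` scores every row with the model
    trained on all rows (in-sample stacking, kept as an explicit toggle).
    """
    if specs is None:
        specs = default_specs()
    specs = list(specs)
    if not specs:
        raise ValueError("specs must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_folds(y, n_folds)
    columns: dict[str, np.ndarray] = {}
    aucs: dict[str, float] = {}
    full_models: dict[str, object] = {}
    fold_of = None
    for spec in specs:
        full = make_learner(spec, seed=seed)
        full.fit(X, y)
        full_models[spec.column_name] = full
        if oof:
            col, auc, fold_of = oof_predict(spec, X, y, n_folds=n_folds, seed=seed)
        else:
            col = _positive_proba(full, X)
            auc = float(roc_auc_score(y, col))
            fold_of = np.full(len(y), -1)
        columns[spec.column_name] = col
        aucs[spec.column_name] = auc
    return StackingResult(
        columns=pd.DataFrame(columns),
        fold_assignment=fold_of,
        per_learner_auc=aucs,
        fitted_full_models=full_models,
        specs=specs,
        seed=seed,
        n_folds=n_folds,
    )


#: Random-search spaces for hyperparameter tuning, sampled log-uniformly
#: where the natural scale is multiplicative.
SEARCH_SPACES: dict[str, dict[str, tuple]] = {
    "SVM": {"C": ("log", 1e-2, 1e2), "gamma": ("log", 1e-4, 1e0)},
    "LR": {"C": ("log", 1e-3, 1e2)},
    "LDA": {"shrinkage": ("uniform", 0.0, 1.0)},
    "LightGBM": {"num_leaves": ("int", 8, 128),
                 "n_estimators": ("int", 50, 400),
                 "learning_rate": ("log", 1e-2, 3e-1)},
    "XGB": {"max_depth": ("int", 2, 8),
            "n_estimators": ("int", 50, 400),
            "learning_rate": ("log", 1e-2, 3e-1)},
    "RF": {"n_estimators": ("int", 50, 400), "max_depth": ("int", 3, 20)},
    "GBDT": {"n_estimators": ("int", 50, 300),
             "learning_rate": ("log", 1e-2, 3e-1)},
    "KNN": {"n_neighbors": ("int", 3, 31)},
    "DT": {"max_depth": ("int", 2, 20)},
    "NB": {"var_smoothing": ("log", 1e-11, 1e-7)},
    "BG": {"n_estimators": ("int", 10, 100)},
}


def _sample_hp(space: dict[str, tuple], rng: np.random.Generator) -> dict:
    hp = {}
    for name, (kind, lo, hi) in space.items():
        if kind == "log":
            hp[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif kind == "uniform":
            hp[name] = float(rng.uniform(lo, hi))
        elif kind == "int":
            hp[name] = int(rng.integers(lo, hi + 1))
        else:  # pragma: no cover
            raise ValueError(kind)
    return hp


def tune_learner(
    spec: BaseLearnerSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    n_iter: int = 20,
    seed: int = 0,
) -> tuple[BaseLearnerSpec, float]:
    """Random hyperparameter search maximizing mean CV AUC.

    Draws ``n_iter`` configurations from the learner's search space and
    evaluates each by stratified ``n_folds`` cross-validated AUC; ties go
    to the first-sampled configuration.  Returns (tuned spec, best AUC).
    """
    space = SEARCH_SPACES.get(spec.name)
    if not space:
        raise ValueError(f"no search space defined for {spec.name!r}")
    if spec.name == "LDA":
        # shrinkage requires the lsqr solver
        base_extra = {"solver": "lsqr"}
    else:
        base_extra = {}
    rng = np.random.default_rng(seed)
    best: tuple[float, BaseLearnerSpec] | None = None
    for _ in range(n_iter):
        hp = {**base_extra, **_sample_hp(space, rng)}
        candidate = BaseLearnerSpec(spec.name, hp)
        _, auc, _ = oof_predict(candidate, X, y, n_folds=n_folds, seed=seed)
        if best is None or auc > best[0]:
            best = (auc, candidate)
    assert best is not None
    return best[1], best[0]
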