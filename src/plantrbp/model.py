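"""Model / Results objects tying the whole pipeline together.

:class:`RBPEnsembleModel` is built from labeled sequences and a
:class:`RunConfig`; its :meth:`~RBPEnsembleModel.fit` runs the full
pipeline — k-peptide encoding, out-of-fold stacking of the base learners,
correlation pruning of the prediction columns, and training of the
convolutional classifier — and returns an :class:`RBPEnsembleResults`
carrying the fitted components, diagnostics, and a ``summary()`` table.
Cross-validation refits the entire pipeline inside each fold so no test
row ever touches a fitted component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import evaluate as ev
from .features import FeatureMatrix, append_columns, encode_dataset
from .seqio import LabeledSequence
from .selection import DEFAULT_ALLOW_LIST, DEFAULT_THRESHOLD, SelectionReport, select_features
from .stacking import BaseLearnerSpec, StackingResult, build_stack, default_specs
from .textcnn import ImprovedTextCNN, TextCNNConfig, TrainingHistory


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    The defaults reproduce the reference setup: k in {1, 2} (420 raw
    features), four base learners (SVM, LR, LDA, LightGBM) adding four
    prediction columns for a 424-dim fused vector, correlation threshold
    0.80 with the SVM/LDA pair allow-listed, kernel sizes 3/4/5 with 64
    filters, patience 5, at most 50 epochs.
    """

    ks: tuple[int, ...] = (1, 2)
    specs: list[BaseLearnerSpec] = field(default_factory=default_specs)
    threshold: float = DEFAULT_THRESHOLD
    allow_list: frozenset = DEFAULT_ALLOW_LIST
    textcnn: TextCNNConfig = field(default_factory=TextCNNConfig)
    stack_folds: int = 5
    oof: bool = True
    val_fraction: float = 0.1
    seed: int = 0

    def to_jsonable(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["allow_list"] = [sorted(p) for p in self.allow_list]
        d["specs"] = [{"name": s.name, "hyperparameters": dict(s.hyperparameters)}
                      for s in self.specs]
        return d


def _labels_of(sequences: Sequence[LabeledSequence]) -> np.ndarray:
    labels = [s.label for s in sequences]
    if any(l is None for l in labels):
        raise ValueError("all sequences must carry a binary label for fitting")
    return np.asarray(labels, dtype=int)


class RBPEnsembleModel:
    """The RBP prediction model, built from labeled sequences."""

    def __init__(self, sequences: Sequence[LabeledSequence],
                 config: RunConfig | None = None):
        if not sequences:
            raise ValueError("no sequences supplied")
        self.sequences = list(sequences)
        self.config = config or RunConfig()

    @classmethod
    def from_fasta(cls, pos_path, neg_path, config: RunConfig | None = None
                   ) -> "RBPEnsembleModel":
        from .seqio import load_dataset

        return cls(load_dataset(pos_path, neg_path), config)

    @classmethod
    def from_benchmark(cls, spec, config: RunConfig | None = None
                       ) -> "RBPEnsembleModel":
        from .simulate import generate

        return cls(generate(spec), config)

    # -- pipeline stages ------------------------------------------------

    def _encode(self, sequences: Sequence[LabeledSequence]) -> FeatureMatrix:
        return encode_dataset(sequences, self.config.ks)

    def fit(self) -> "RBPEnsembleResults":
        """Fit the full pipeline on all sequences."""
        cfg = self.config
        y = _labels_of(self.sequences)
        base = self._encode(self.sequences)
        stack = build_stack(base.values, y, cfg.specs, n_folds=cfg.stack_folds,
                            seed=cfg.seed, oof=cfg.oof)
        report = select_features(stack.columns, stack.per_learner_auc,
                                 threshold=cfg.threshold,
                                 allow_list=cfg.allow_list)
        fused = append_columns(base, stack.columns[report.kept])
        cnn_cfg = replace(cfg.textcnn, input_dim=fused.n, seed=cfg.textcnn.seed)
        idx_tr, idx_va = train_test_split(
            np.arange(len(y)), test_size=cfg.val_fraction, stratify=y,
            random_state=cfg.seed)
        cnn = ImprovedTextCNN(cnn_cfg)
        history = cnn.fit(fused.values[idx_tr], y[idx_tr],
                          fused.values[idx_va], y[idx_va])
        return RBPEnsembleResults(
            model=self,
            stacking=stack,
            selection=report,
            cnn=cnn,
            history=history,
            feature_names=list(fused.column_names),
        )

    def cross_validate(self, n_folds: int = 5, seed: int | None = None,
                       averaging: str = "binary") -> ev.CVSummary:
        """Stratified k-fold CV refitting the whole pipeline per fold."""
        seed = self.config.seed if seed is None else seed
        config = self.config

        def factory():
            return _PipelineAdapter(config)

        return ev.cross_validate(factory, self.sequences, n_folds=n_folds,
                                 seed=seed, averaging=averaging)


class _PipelineAdapter:
    """fit/predict_proba facade over the model, for the CV harness."""

    def __init__(self, config: RunConfig):
        self.config = config

    def fit(self, sequences: Sequence[LabeledSequence]) -> None:
        self.results_ = RBPEnsembleModel(sequences, self.config).fit()

    def predict_proba(self, sequences: Sequence[LabeledSequence]) -> np.ndarray:
        return self.results_.predict(sequences)["probability"].to_numpy()


class RBPEnsembleResults:
    """Fitted pipeline bundle: estimates, diagnostics, prediction."""

    def __init__(self, model: RBPEnsembleModel, stacking: StackingResult,
                 selection: SelectionReport, cnn: ImprovedTextCNN,
                 history: TrainingHistory, feature_names: list[str]):
        self.model = model
        self.stacking = stacking
        self.selection = selection
        self.cnn = cnn
        self.history = history
        self.feature_names = feature_names

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def predict(self, sequences: Sequence[LabeledSequence]) -> pd.DataFrame:
        """Score unseen sequences: id, probability, predicted label."""
        base = self.model._encode(sequences)
        pred_cols = self.stacking.predict_columns(base.values)
        fused = append_columns(base, pred_cols[self.selection.kept])
        proba = self.cnn.predict_proba(fused.values)
        return pd.DataFrame({
            "id": [s.id for s in sequences],
            "probability": proba,
            "label": (proba >= 0.5).astype(int),
        })

    def evaluate(self, sequences: Sequence[LabeledSequence],
                 averaging: str = "binary") -> ev.MetricSet:
        """Metrics on an independent labeled set."""
        y = _labels_of(sequences)
        scores = self.predict(sequences)["probability"].to_numpy()
        return ev.evaluate_predictions(y, scores, averaging=averaging)

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = []
        cfg = self.model.config
        lines.append("RBP ensemble model fit")
        lines.append("=" * 58)
        lines.append(f"sequences: {len(self.model.sequences)}   "
                     f"ks={list(cfg.ks)}   fused features: {self.n_features}")
        lines.append("")
        lines.append("base learners (out-of-fold AUC):")
        for name, auc in self.stacking.per_learner_auc.items():
            kept = "kept" if name in self.selection.kept else "dropped"
            lines.append(f"  {name:<24s} {auc:7.4f}   {kept}")
        if self.selection.dropped:
            lines.append("")
            lines.append("pruned by correlation (|r| > "
                         f"{self.selection.threshold}):")
            for d in self.selection.dropped:
                lines.append(f"  {d['feature']} vs {d['competing_feature']}: "
                             f"r={d['r']:+.3f}, AUC {d['auc_dropped']:.3f} < "
                             f"{d['auc_kept']:.3f}")
        h = self.history
        lines.append("")
        lines.append(f"classifier: stopped epoch {h.stopped_epoch}, best epoch "
                     f"{h.best_epoch}, val loss {min(h.val_loss):.4f}, "
                     f"val acc {h.val_acc[h.best_epoch - 1]:.4f}")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Persist the bundle (models, selection report, config manifest)."""
        import joblib

        out_dir = Path(out_dir)
        (out_dir / "models").mkdir(parents=True, exist_ok=True)
        (out_dir / "reports").mkdir(exist_ok=True)
        self.cnn.save(out_dir / "models" / "textcnn")
        joblib.dump(self.stacking.fitted_full_models,
                    out_dir / "models" / "base_learners.joblib")
        self.selection.to_json(out_dir / "reports" / "selection.json")
        self.stacking.save(out_dir / "reports",
                           ids=[s.id for s in self.model.sequences])
        self.history.to_csv(out_dir / "reports" / "training_history.csv")
        manifest = {
            "config": self.model.config.to_jsonable(),
            "feature_names_tail": self.feature_names[-10:],
            "n_features": self.n_features,
            "versions": _versions(),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _versions() -> dict[str, str]:
    import lightgbm
    import sklearn

    import plantrbp

    return {
        "plantrbp": plantrbp.__version__,
        "numpy": np.__version__,
        "sklearn": sklearn.__version__,
        "lightgbm": lightgbm.__version__,
    }


# -- ablation ----------------------------------------------------------


@dataclass
class AblationReport:
    """Incremental feature-set comparison with paired significance tests.

    ``D0`` is the raw k-peptide encoding; ``D1``..``D4`` add the SVM, LR,
    LDA, and LightGBM prediction columns one at a time.  All sets share
    identical fold partitions, a validity requirement of the paired tests.
    """

    set_names: list[str]
    widths: dict[str, int]
    per_fold: dict[str, list[ev.MetricSet]]
    comparisons: dict[str, dict[str, ev.PairedComparison]]
    n_folds: int
    seed: int

    def metrics_table(self, ddof: int = 0) -> pd.DataFrame:
        rows = []
        for name in self.set_names:
            folds = self.per_fold[name]
            row = {"feature_set": name, "width": self.widths[name]}
            for metric in ev.METRIC_NAMES:
                vals = [getattr(f, metric) for f in folds]
                if any(v is None for v in vals):
                    row[metric] = "undefined"
                else:
                    mean, std = ev.aggregate_folds(vals, ddof=ddof)
                    row[metric] = f"{mean:.2f} ± {std:.2f}"
            rows.append(row)
        return pd.DataFrame(rows)

    def pvalue_table(self) -> pd.DataFrame:
        rows = []
        for pair, tests in self.comparisons.items():
            row = {"comparison": pair}
            for metric in ("ACC", "MCC"):
                t = tests.get(metric)
                row[f"p_value_{metric}"] = t.p_value if t else np.nan
                row[f"shapiro_p_{metric}"] = t.shapiro_p if t else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def run_ablation(
    sequences: Sequence[LabeledSequence],
    config: RunConfig | None = None,
    n_folds: int = 10,
) -> AblationReport:
    """Evaluate D0..D4 under identical folds with adjacent paired tests.

    Per fold, the four base learners are stacked once on the training
    portion (out-of-fold columns for training rows, full-model scores for
    test rows); each feature set then trains its own convolutional
    classifier on the same partition.
    """
    config = config or RunConfig()
    y = _labels_of(sequences)
    base = encode_dataset(sequences, config.ks)
    specs = config.specs
    set_names = [f"D{i}" for i in range(len(specs) + 1)]
    widths = {f"D{i}": base.n + i for i in range(len(specs) + 1)}
    per_fold: dict[str, list[ev.MetricSet]] = {n: [] for n in set_names}
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=config.seed)
    for fold, (tr, te) in enumerate(skf.split(base.values, y)):
        stack = build_stack(base.values[tr], y[tr], specs,
                            n_folds=config.stack_folds, seed=config.seed,
                            oof=config.oof)
        test_cols = stack.predict_columns(base.values[te])
        col_names = [s.column_name for s in specs]
        itr, iva = train_test_split(np.arange(len(tr)),
                                    test_size=config.val_fraction,
                                    stratify=y[tr], random_state=config.seed)
        for i, name in enumerate(set_names):
            use = col_names[:i]
            Xtr = np.column_stack([base.values[tr]] +
                                  [stack.columns[c].to_numpy() for c in use]) \
                if use else base.values[tr]
            Xte = np.column_stack([base.values[te]] +
                                  [test_cols[c].to_numpy() for c in use]) \
                if use else base.values[te]
            cnn_cfg = replace(config.textcnn, input_dim=Xtr.shape[1],
                              seed=config.textcnn.seed + fold)
            cnn = ImprovedTextCNN(cnn_cfg)
            cnn.fit(Xtr[itr], y[tr][itr], Xtr[iva], y[tr][iva])
            scores = cnn.predict_proba(Xte)
            per_fold[name].append(ev.evaluate_predictions(y[te], scores))
    comparisons: dict[str, dict[str, ev.PairedComparison | None]] = {}
    for a, b in zip(set_names[:-1], set_names[1:]):
        pair: dict[str, ev.PairedComparison | None] = {}
        for metric in ("ACC", "MCC"):
            va = [getattr(f, metric) for f in per_fold[a]]
            vb = [getattr(f, metric) for f in per_fold[b]]
            if any(v is None for v in va + vb):
                pair[metric] = None  # metric undefined in some fold
                continue
            try:
                pair[metric] = ev.compare_feature_sets(va, vb)
            except ev.UndefinedMetricError:
                # identical per-fold values: the paired test is undefined
                pair[metric] = None
        comparisons[f"{b} vs. {a}"] = pair
    return AblationReport(set_names=set_names, widths=widths,
                          per_fold=per_fold, comparisons=comparisons,
                          n_folds=n_folds, seed=config.seed)
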