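"""Pearson-correlation analysis and AUC-guided feature pruning.

Candidate columns (typically the base-learner prediction columns) are
screened pairwise: whenever |r| exceeds the threshold (default 0.80), the
member with the lower single-column AUC is dropped, unless the pair is on
an allow-list.  The default allow-list keeps the SVM/LDA prediction pair
despite their high correlation, because the two classifiers' mechanisms
(margin maximization vs. linear discriminants) are complementary and both
columns carry high AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix

#: Feature pairs exempt from pruning by default.
DEFAULT_ALLOW_LIST = frozenset({frozenset({"SVM_Pred_Result", "LDA_Pred_Result"})})

DEFAULT_THRESHOLD = 0.80


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (zero variance)."""


class CorrelationEntry(NamedTuple):
    feature_a: str
    feature_b: str
    r: float


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient Cov(x, y) / (sd_x * sd_y).

    Raises :class:`UndefinedCorrelationError` when either vector has zero
    variance — an undefined correlation is never silently reported as 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        which = "x" if sx == 0.0 else "y"
        raise UndefinedCorrelationError(f"zero variance in {which}")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov / (sx * sy))


def _columns_of(data) -> dict[str, np.ndarray]:
    if isinstance(data, FeatureMatrix):
        return {name: data.column(name) for name in data.column_names}
    if isinstance(data, pd.DataFrame):
        return {str(c): data[c].to_numpy(dtype=float) for c in data.columns}
    return {str(k): np.asarray(v, dtype=float) for k, v in dict(data).items()}


def correlation_table(
    data, subset: Sequence[str] | None = None
) -> tuple[list[CorrelationEntry], list[str]]:
    """All unordered pairwise correlations among the chosen columns.

    Returns (entries sorted by |r| descending, zero-variance column names).
    Zero-variance columns are excluded from the table and reported, never
    silently dropped.
    """
    cols = _columns_of(data)
    if subset is not None:
        missing = [n for n in subset if n not in cols]
        if missing:
            raise KeyError(f"columns not present: {missing}")
        cols = {n: cols[n] for n in subset}
    degenerate = [n for n, v in cols.items() if np.asarray(v).std() == 0.0]
    live = [n for n in cols if n not in degenerate]
    entries = [
        CorrelationEntry(a, b, pearson(cols[a], cols[b]))
        for i, a in enumerate(live)
        for b in live[i + 1 :]
    ]
    entries.sort(key=lambda e: (-abs(e.r), e.feature_a, e.feature_b))
    return entries, degenerate


@dataclass
class SelectionReport:
    """Outcome of correlation-based pruning."""

    threshold: float
    entries: list[CorrelationEntry]
    dropped: list[dict]
    kept: list[str]
    allow_list: frozenset[frozenset[str]]
    zero_variance: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold": self.threshold,
            "entries": [e._asdict() for e in self.entries],
            "dropped": self.dropped,
            "kept": self.kept,
            "allow_list": [sorted(p) for p in self.allow_list],
            "zero_variance": self.zero_variance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def entries_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)


def select_features(
    candidates,
    auc: Mapping[str, float],
    threshold: float = DEFAULT_THRESHOLD,
    allow_list: Iterable[Iterable[str]] | None = None,
) -> SelectionReport:
    """Prune correlated candidate columns, keeping the higher-AUC member.

    Pairs are processed by |r| descending (name order breaks ties) so the
    outcome is deterministic when three or more columns are mutually
    correlated; a feature already dropped is skipped in later pairs.

    Parameters
    ----------
    candidates
        Named columns (FeatureMatrix, DataFrame, or mapping name -> vector).
    auc
        Single-column AUC for every candidate (used to pick the survivor).
    threshold
        Absolute-correlation cutoff; pairs at or below it are untouched.
    allow_list
        Pairs exempt from pruning.  Defaults to the SVM/LDA prediction pair.
    """
    cols = _columns_of(candidates)
    missing = [n for n in cols if n not in auc]
    if missing:
        raise ValueError(f"missing AUC for candidates: {missing}")
    allow = (
        DEFAULT_ALLOW_LIST
        if allow_list is None
        else frozenset(frozenset(p) for p in allow_list)
    )
    entries, degenerate = correlation_table(cols)
    dropped: list[dict] = []
    out: set[str] = set()
    for a, b, r in entries:
        if abs(r) <= threshold or a in out or b in out:
            continue
        if frozenset({a, b}) in allow:
            continue
        loser, winner = (a, b) if auc[a] < auc[b] else (b, a)
        if auc[a] == auc[b]:
            # deterministic tie-break: drop the lexicographically later name
            winner, loser = sorted((a, b))
        out.add(loser)
        dropped.append(
            {
                "feature": loser,
                "reason": f"|r|={abs(r):.4f} > {threshold} with {winner}",
                "competing_feature": winner,
                "r": r,
                "auc_dropped": auc[loser],
                "auc_kept": auc[winner],
            }
        )
    kept = [n for n in cols if n not in out and n not in degenerate]
    report = SelectionReport(
        threshold=threshold,
        entries=entries,
        dropped=dropped,
        kept=kept,
        allow_list=allow,
        zero_variance=degenerate,
    )
    _audit(report, cols)
    return report


def _audit(report: SelectionReport, cols: Mapping[str, np.ndarray]) -> None:
    """Post-condition: no surviving non-allow-listed pair exceeds threshold."""
    kept = report.kept
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            if frozenset({a, b}) in report.allow_list:
                continue
            r = pearson(cols[a], cols[b])
            if abs(r) > report.threshold:  # pragma: no cover - defensive
                raise AssertionError(
                    f"selection audit failed: kept pair ({a}, {b}) has |r|={abs(r):.4f}"
                )


def save_correlation_csv(entries: Sequence[CorrelationEntry], path: str | Path) -> None:
    pd.DataFrame(entries).to_csv(path, index=False)


def plot_heatmap(
    data, path: str | Path, top_n: int = 10, subset: Sequence[str] | None = None
) -> None:
    """Emit a correlation heatmap of the top-N most correlated columns."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries, _ = correlation_table(data, subset)
    names: list[str] = []
    for e in entries:
        for n in (e.feature_a, e.feature_b):
            if n not in names:
                names.append(n)
        if len(names) >= top_n:
            break
    names = names[:top_n]
    cols = _columns_of(data)
    mat = np.corrcoef(np.column_stack([cols[n] for n in names]), rowvar=False)
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(names), 1 + 0.6 * len(names)))
    im = ax.imshow(mat, vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=7)
    ax.set_yticks(range(len(names)), names, fontsize=7)
    for i in range(len(names)):
        for j in range(len(names)):
            ax.text(j, i, f"{mat[i, j]:.2f}", ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
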