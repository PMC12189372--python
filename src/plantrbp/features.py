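"""k-peptide composition (KPC) encoding and feature-matrix assembly.

A protein of length L contains L - k + 1 overlapping windows of length k.
The KPC vector for peptide length k assigns to each of the 20^k possible
k-peptides its window frequency

    f_i = N_i / (L - k + 1),

where N_i counts occurrences of the i-th k-peptide.  k = 1 is the classic
amino-acid composition (AAC, 20 dims), k = 2 the dipeptide composition
(DPC, 400 dims), k = 3 the tripeptide composition (TPC, 8000 dims).
Concatenating k = 1 and k = 2 yields the 420-dim encoding used by default;
appending the four base-learner prediction columns gives the 424-dim input
of the convolutional classifier.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, LabeledSequence

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class SequenceTooShortError(ValueError):
    """Raised when a sequence is shorter than the requested peptide length."""


@lru_cache(maxsize=8)
def kpc_names(k: int) -> tuple[str, ...]:
    """All 20^k k-peptide strings in lexicographic order over AMINO_ACIDS."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return tuple("".join(p) for p in itertools.product(AMINO_ACIDS, repeat=k))


@dataclass(frozen=True)
class KPCVector:
    """The 20^k frequency vector of one sequence for one peptide length."""

    k: int
    values: np.ndarray
    names: tuple[str, ...]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def _residue_indices(seq: LabeledSequence) -> np.ndarray:
    try:
        return np.fromiter((_AA_INDEX[c] for c in seq.residues), dtype=np.int64,
                           count=len(seq.residues))
    except KeyError as exc:
        raise ValueError(
            f"record {seq.id!r} contains nonstandard residue {exc.args[0]!r}; "
            "sanitize before encoding"
        ) from None


def kpc_encode(seq: LabeledSequence, k: int) -> KPCVector:
    """Encode one sequence as its k-peptide composition.

    Raises
    ------
    SequenceTooShortError
        If the sequence has fewer than k residues.
    """
    names = kpc_names(k)
    L = len(seq.residues)
    if L < k:
        raise SequenceTooShortError(
            f"sequence_shorter_than_k: record {seq.id!r} has length {L} < k={k}"
        )
    idx = _residue_indices(seq)
    # Encode each window as a base-20 integer; bincount tallies all windows.
    codes = np.zeros(L - k + 1, dtype=np.int64)
    for j in range(k):
        codes = codes * 20 + idx[j : L - k + 1 + j]
    counts = np.bincount(codes, minlength=20**k).astype(float)
    return KPCVector(k=k, values=counts / (L - k + 1), names=names)


@dataclass
class FeatureMatrix:
    """An m x n matrix of named real features for m sequences.

    ``column_names`` are k-peptide strings and/or appended prediction-column
    names such as ``"SVM_Pred_Result"``.
    """

    ids: list[str]
    column_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.ids), len(self.column_names)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape}, "
                f"{len(self.ids)} ids x {len(self.column_names)} columns"
            )
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("column names must be unique")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.column_names.index(n) for n in names]
        return FeatureMatrix(list(self.ids), list(names), self.values[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.column_names)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().rename_axis("id").to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy())


def encode_dataset(
    seqs: Sequence[LabeledSequence], ks: Sequence[int] = (1, 2)
) -> FeatureMatrix:
    """Encode a dataset as concatenated KPC blocks, one per k in order.

    The feature dimension is the sum of 20^k over the requested k values:
    420 for ks = (1, 2), 8420 for ks = (1, 2, 3).

    Raises
    ------
    SequenceTooShortError
        Aggregated over all sequences shorter than max(ks), listing ids.
    """
    ks = list(ks)
    if not ks or any(k < 1 for k in ks):
        raise ValueError(f"ks must be positive integers, got {ks}")
    kmax = max(ks)
    too_short = [s.id for s in seqs if len(s.residues) < kmax]
    if too_short:
        raise SequenceTooShortError(
            f"sequence_shorter_than_k: {len(too_short)} records shorter than "
            f"k={kmax}: {too_short[:20]}"
        )
    names = [name for k in ks for name in kpc_names(k)]
    values = np.empty((len(seqs), len(names)))
    for i, seq in enumerate(seqs):
        values[i] = np.concatenate([kpc_encode(seq, k).values for k in ks])
    return FeatureMatrix([s.id for s in seqs], names, values)


def append_columns(
    base: FeatureMatrix, extra: Mapping[str, np.ndarray] | pd.DataFrame
) -> FeatureMatrix:
    """Append named real columns (e.g. base-learner predictions) to a matrix."""
    if isinstance(extra, pd.DataFrame):
        extra = {str(c): extra[c].to_numpy() for c in extra.columns}
    if not extra:
        return FeatureMatrix(list(base.ids), list(base.column_names), base.values.copy())
    dup = set(extra) & set(base.column_names)
    if dup:
        raise ValueError(f"duplicate column names: {sorted(dup)}")
    cols = []
    for name, col in extra.items():
        col = np.asarray(col, dtype=float).ravel()
        if col.shape[0] != base.n_rows:
            raise ValueError(
                f"column {name!r} has {col.shape[0]} rows, expected {base.n_rows}"
            )
        cols.append(col)
    return FeatureMatrix(
        list(base.ids),
        list(base.column_names) + list(extra),
        np.column_stack([base.values] + cols),
    )
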