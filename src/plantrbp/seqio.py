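"""Reading, validating, and writing labeled protein sequence data.

Sequences are plain amino-acid strings over the 20-letter standard
alphabet.  Labels are binary: 1 for RNA-binding proteins (RBPs), 0 for
non-RBPs, or ``None`` for prediction-only inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: Canonical ordering of the 20 standard amino acids.  All k-peptide
#: feature names derive from this ordering, so it must never change.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

SanitizePolicy = Literal["drop_residue", "drop_record"]


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed."""


class DuplicateIdError(ValueError):
    """Raised when record identifiers collide within one dataset."""


@dataclass(frozen=True)
class LabeledSequence:
    """A protein sequence with identifier and optional binary class label."""

    id: str
    residues: str
    label: int | None = None
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def is_standard(self) -> bool:
        """True if every residue is one of the 20 standard amino acids."""
        return bool(self.residues) and set(self.residues) <= _AA_SET


@dataclass(frozen=True)
class Rejection:
    """A record removed during sanitization, with the reason."""

    id: str
    reason: str


def read_fasta(path: str | Path, label: int | None = None) -> list[LabeledSequence]:
    """Read a FASTA file into an ordered list of :class:`LabeledSequence`.

    The identifier is the header token before the first whitespace; the
    remainder of the header line is kept as the description.  Sequence
    lines are concatenated and uppercased.

    Parameters
    ----------
    path
        FASTA file path.
    label
        Optional binary label attached to every record.

    Raises
    ------
    FastaParseError
        If sequence data precedes the first header line.
    DuplicateIdError
        If two records share an identifier.
    """
    path = Path(path)
    with open(path) as handle:
        # Locate the first non-blank line so a malformed file is reported
        # with its line number rather than silently skipped.
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before first "
                        f"'>' header"
                    )
                break
        else:
            logger.warning("FASTA file %s is empty", path)
            return []
        handle.seek(0)
        records = [
            LabeledSequence(
                id=title.split()[0] if title.split() else title,
                residues=seq.replace(" ", "").upper(),
                label=label,
                description=title.split(maxsplit=1)[1] if len(title.split(maxsplit=1)) > 1 else "",
            )
            for title, seq in SimpleFastaParser(handle)
        ]
    seen: dict[str, int] = {}
    dups = []
    for rec in records:
        seen[rec.id] = seen.get(rec.id, 0) + 1
        if seen[rec.id] == 2:
            dups.append(rec.id)
    if dups:
        raise DuplicateIdError(f"{path}: duplicate record ids: {sorted(dups)}")
    return records


def write_fasta(records: Iterable[LabeledSequence], path: str | Path, width: int = 60) -> None:
    """Write records to a FASTA file, wrapping sequence lines at ``width``."""
    with open(path, "w") as out:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            out.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


def sanitize(
    seq: LabeledSequence, policy: SanitizePolicy = "drop_residue"
) -> LabeledSequence | Rejection:
    """Remove or reject nonstandard residues (B, J, O, U, X, Z, gaps, stops).

    With ``drop_residue`` the offending characters are removed; with
    ``drop_record`` any nonstandard character rejects the whole record.
    A sequence left empty by sanitization is always rejected.
    """
    if seq.is_standard():
        return seq
    nonstandard = set(seq.residues) - _AA_SET
    if policy == "drop_record" and nonstandard:
        return Rejection(seq.id, "nonstandard_residue")
    cleaned = "".join(c for c in seq.residues if c in _AA_SET)
    if not cleaned:
        return Rejection(seq.id, "empty_after_sanitize")
    return replace(seq, residues=cleaned)


def sanitize_dataset(
    seqs: Iterable[LabeledSequence], policy: SanitizePolicy = "drop_residue"
) -> tuple[list[LabeledSequence], list[Rejection]]:
    """Sanitize a whole dataset, returning kept records and rejections."""
    kept: list[LabeledSequence] = []
    rejected: list[Rejection] = []
    for seq in seqs:
        out = sanitize(seq, policy)
        if isinstance(out, Rejection):
            rejected.append(out)
        else:
            kept.append(out)
    return kept, rejected


def load_dataset(
    pos_path: str | Path,
    neg_path: str | Path,
    policy: SanitizePolicy = "drop_residue",
) -> list[LabeledSequence]:
    """Load a positive/negative FASTA pair into one labeled dataset.

    Positives are labeled 1, negatives 0.  If an identifier occurs in both
    files, ids are namespaced as ``pos:<id>`` / ``neg:<id>``.  Records that
    fail sanitization are dropped with a logged warning.
    """
    pos = read_fasta(pos_path, label=1)
    neg = read_fasta(neg_path, label=0)
    if not pos:
        raise ValueError(f"no records in positive file {pos_path}")
    if not neg:
        raise ValueError(f"no records in negative file {neg_path}")
    collisions = {r.id for r in pos} & {r.id for r in neg}
    if collisions:
        pos = [replace(r, id=f"pos:{r.id}") if r.id in collisions else r for r in pos]
        neg = [replace(r, id=f"neg:{r.id}") if r.id in collisions else r for r in neg]
    kept, rejected = sanitize_dataset(pos + neg, policy)
    if rejected:
        logger.warning("dropped %d records during sanitization: %s",
                       len(rejected), [r.id for r in rejected][:10])
    logger.info("loaded %d positives, %d negatives",
                sum(1 for s in kept if s.label == 1),
                sum(1 for s in kept if s.label == 0))
    return kept


def read_label_table(
    fasta_path: str | Path, table_path: str | Path
) -> list[LabeledSequence]:
    """Load one FASTA plus a TSV label table with columns (id, label)."""
    import csv

    labels: dict[str, int] = {}
    with open(table_path) as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].lower() in ("id", "#id"):
                continue
            labels[row[0]] = int(row[1])
    records = read_fasta(fasta_path)
    missing = [r.id for r in records if r.id not in labels]
    if missing:
        raise ValueError(f"no label for ids: {missing[:10]}")
    return [replace(r, label=labels[r.id]) for r in records]
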