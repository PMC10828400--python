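"""Read, validate, write, and partition labeled peptide datasets.

Peptides are short stretches of consecutive amino-acid residues from an
antigen protein, each optionally labeled as epitope (1) or non-epitope (0).
Supported on-disk formats:

* CSV with columns ``sequence,label[,id]`` (header required, UTF-8);
* FASTA where the label rides in the header as ``>id|label=<0|1>``.

Non-canonical residue codes (B, J, O, U, X, Z and anything else outside the
20-letter alphabet) are rejected under the default ``strict`` policy or
discarded with a logged warning under ``drop``; all downstream k-mer math
assumes the canonical alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from epiboost._alphabet import CANONICAL_SET

logger = logging.getLogger(__name__)

__all__ = [
    "Peptide",
    "EpitopeDataset",
    "FoldAssignment",
    "PeptideValidationError",
    "PeptideParseError",
    "read_peptides",
    "write_peptides",
    "stratified_folds",
    "greedy_identity_filter",
]


class PeptideValidationError(ValueError):
    """A peptide violates the alphabet/label contract."""


class PeptideParseError(ValueError):
    """A file record could not be parsed into a peptide."""


@dataclass(frozen=True)
class Peptide:
    """A single amino-acid sequence with an optional binary epitope label."""

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise PeptideValidationError(f"peptide {self.id!r}: empty sequence")
        bad = set(self.sequence) - CANONICAL_SET
        if bad:
            raise PeptideValidationError(
                f"peptide {self.id!r}: non-canonical residue(s) "
                f"{''.join(sorted(bad))} in sequence {self.sequence!r}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise PeptideValidationError(
                f"peptide {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class EpitopeDataset:
    """An ordered collection of peptides with a name and provenance tag."""

    name: str
    peptides: list[Peptide] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i: int) -> Peptide:
        return self.peptides[i]

    @property
    def n_pos(self) -> int:
        return sum(1 for p in self.peptides if p.label == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for p in self.peptides if p.label == 0)

    def labels(self) -> np.ndarray:
        """Label vector; raises if any peptide is unlabeled."""
        self.require_labeled()
        return np.array([p.label for p in self.peptides], dtype=int)

    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def require_labeled(self) -> None:
        for p in self.peptides:
            if p.label is None:
                raise PeptideValidationError(
                    f"dataset {self.name!r}: peptide {p.id!r} has no label"
                )

    def require_both_classes(self) -> None:
        self.require_labeled()
        if self.n_pos < 1 or self.n_neg < 1:
            raise PeptideValidationError(
                f"dataset {self.name!r}: needs >=1 positive and >=1 negative "
                f"(got {self.n_pos} / {self.n_neg})"
            )

    def subset(self, indices: Sequence[int], name: str | None = None) -> "EpitopeDataset":
        return EpitopeDataset(
            name=name or f"{self.name}[subset]",
            peptides=[self.peptides[i] for i in indices],
            provenance=self.provenance,
        )


@dataclass
class FoldAssignment:
    """A stratified k-fold partition: one fold index in [0, k) per peptide."""

    k: int
    assignment: np.ndarray  # shape (n,), dtype int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)

    def to_csv(self, dataset: EpitopeDataset, path: str | Path) -> None:
        pd.DataFrame({"id": dataset.ids(), "fold": self.assignment}).to_csv(
            path, index=False
        )


def _normalize_sequence(
    seq: str, pid: str, policy: str
) -> str | None:
    """Upper-case and validate; returns None when dropped under policy 'drop'."""
    seq = seq.strip().upper()
    bad = set(seq) - CANONICAL_SET
    if not seq:
        raise PeptideParseError(f"record {pid!r}: empty sequence")
    if bad:
        if policy == "strict":
            raise PeptideValidationError(
                f"record {pid!r}: non-canonical residue(s) "
                f"{''.join(sorted(bad))} under strict policy"
            )
        if policy == "drop":
            logger.warning(
                "dropping peptide %r: non-canonical residue(s) %s",
                pid,
                "".join(sorted(bad)),
            )
            return None
        raise ValueError(f"unknown non-canonical policy {policy!r}")
    return seq


def _parse_label_token(value: str, where: str) -> int:
    value = value.strip()
    if value not in ("0", "1"):
        raise PeptideParseError(f"{where}: label must be 0 or 1, got {value!r}")
    return int(value)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".fa", ".fasta", ".faa"):
        return "fasta"
    if suffix in (".csv",):
        return "csv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_peptides(
    path: str | Path,
    format: str | None = None,
    label_policy: str = "strict",
    require_labels: bool = False,
    name: str | None = None,
) -> EpitopeDataset:
    """Read a labeled peptide dataset from FASTA or CSV.

    Parameters
    ----------
    path : file path.
    format : ``"fasta"`` | ``"csv"``; inferred from the suffix when None.
    label_policy : non-canonical residue handling, ``"strict"`` (error) or
        ``"drop"`` (discard with a logged warning).
    require_labels : when True, a record without a label is a parse error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such peptide file: {path}")
    fmt = _infer_format(path, format)
    peptides: list[Peptide] = []

    if fmt == "csv":
        try:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise PeptideParseError(f"{path}: {exc}") from exc
        if "sequence" not in df.columns:
            raise PeptideParseError(f"{path}: missing required column 'sequence'")
        has_label = "label" in df.columns
        if require_labels and not has_label:
            raise PeptideParseError(f"{path}: missing required column 'label'")
        has_id = "id" in df.columns
        for row_no, row in enumerate(df.itertuples(index=False), start=2):
            rec = dict(zip(df.columns, row))
            pid = rec["id"] if has_id and rec.get("id") else f"peptide_{row_no - 1}"
            label: int | None = None
            if has_label and rec["label"] != "":
                label = _parse_label_token(rec["label"], f"{path} line {row_no}")
            elif require_labels:
                raise PeptideParseError(f"{path} line {row_no}: missing label")
            seq = _normalize_sequence(rec["sequence"], pid, label_policy)
            if seq is None:
                continue
            peptides.append(Peptide(id=pid, sequence=seq, label=label))
    elif fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.description
            pid = header.split("|", 1)[0].split()[0] if header else rec.id
            label: int | None = None
            for token in header.split("|")[1:]:
                token = token.strip()
                if token.startswith("label="):
                    label = _parse_label_token(
                        token[len("label="):], f"{path} record {pid!r}"
                    )
            if require_labels and label is None:
                raise PeptideParseError(
                    f"{path} record {pid!r}: no 'label=<0|1>' token in header"
                )
            seq = _normalize_sequence(str(rec.seq), pid, label_policy)
            if seq is None:
                continue
            peptides.append(Peptide(id=pid, sequence=seq, label=label))
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'fasta' or 'csv'")

    return EpitopeDataset(
        name=name or path.stem, peptides=peptides, provenance=f"read from {path}"
    )


def write_peptides(
    dataset: EpitopeDataset, path: str | Path, format: str | None = None
) -> None:
    """Write a dataset to FASTA or CSV; round trips losslessly with read."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        pd.DataFrame(
            {
                "sequence": dataset.sequences(),
                "label": ["" if p.label is None else p.label for p in dataset],
                "id": dataset.ids(),
            }
        ).to_csv(path, index=False)
    elif fmt == "fasta":
        records = []
        for p in dataset:
            header = p.id if p.label is None else f"{p.id}|label={p.label}"
            records.append(SeqRecord(Seq(p.sequence), id=header, description=""))
        SeqIO.write(records, str(path), "fasta")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'fasta' or 'csv'")


def stratified_folds(
    dataset: EpitopeDataset, k: int, seed: int
) -> FoldAssignment:
    """Assign each peptide to one of k folds, stratified by label.

    Per-fold positive counts differ by at most 1 across folds, likewise
    negatives. Deterministic for a fixed seed: each class's indices are
    shuffled then dealt round-robin starting at fold 0.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    dataset.require_labeled()
    labels = dataset.labels()
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos < k or n_neg < k:
        raise ValueError(
            f"need at least k={k} samples per class, got {n_pos} positives "
            f"and {n_neg} negatives"
        )
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(dataset), dtype=int)
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return FoldAssignment(k=k, assignment=assignment)


def greedy_identity_filter(
    dataset: EpitopeDataset, identity_threshold: float
) -> EpitopeDataset:
    """Drop near-duplicate sequences by ungapped identity, first-seen wins.

    Identity is matches/length between *equal-length* sequences only;
    unequal lengths are never compared. This is deliberately not a CD-HIT
    substitute — no alignment, no clustering — just duplicate plumbing.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    kept: list[Peptide] = []
    by_length: dict[int, list[str]] = {}
    for p in dataset:
        group = by_length.setdefault(len(p.sequence), [])
        n = len(p.sequence)
        redundant = any(
            sum(a == b for a, b in zip(p.sequence, q)) / n >= identity_threshold
            for q in group
        )
        if not redundant:
            kept.append(p)
            group.append(p.sequence)
    return EpitopeDataset(
        name=dataset.name,
        peptides=kept,
        provenance=(
            f"{dataset.provenance}; greedy identity filter "
            f"@{identity_threshold:g}".strip("; ")
        ),
    )
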