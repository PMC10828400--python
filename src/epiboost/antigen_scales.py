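"""Dipeptide (AAP) and tripeptide (AAT) antigenicity scales.

An antigenicity scale assigns each k-mer the log ratio of its occurrence
frequency in epitopes versus non-epitopes,

    raw(m) = ln( f+(m) / f-(m) ),

with Laplace smoothing so the ratio is finite when a k-mer is absent from
one class:

    f+(m) = (count_pos(m) + pseudocount) / (total_pos + pseudocount * 20**k)

and analogously for f-. Raw values are then min–max rescaled onto [-1, 1]
over the observed k-mers (the degenerate all-equal case maps to 0). The
natural log is used; the base is a monotone rescaling absorbed by the
min–max step, so it cannot change the normalized ordering.

AAP uses k=2 (dipeptides), AAT uses k=3 (tripeptides). Scales are built
from whatever labeled dataset they are given; in cross-validation the
classifier module rebuilds them from training folds only.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from epiboost._alphabet import CANONICAL_SET, all_kmers
from epiboost.peptide_data import EpitopeDataset, Peptide

logger = logging.getLogger(__name__)

__all__ = [
    "KmerCountTable",
    "KmerScale",
    "ScaleFileError",
    "count_kmers",
    "build_scale",
    "apply_scale",
    "save_scale",
    "load_scale",
]


class ScaleFileError(ValueError):
    """A persisted scale file is malformed."""


@dataclass
class KmerCountTable:
    """Overlapping k-mer window counts per class."""

    k: int
    counts_pos: dict[str, int] = field(default_factory=dict)
    counts_neg: dict[str, int] = field(default_factory=dict)
    total_pos: int = 0
    total_neg: int = 0


@dataclass
class KmerScale:
    """A k-mer -> antigenicity value map (raw log ratio and [-1,1] normalized)."""

    k: int
    raw: dict[str, float]
    normalized: dict[str, float]
    pseudocount: float
    default_value: float = 0.0
    source: str = ""

    def normalized_value(self, kmer: str) -> float:
        return self.normalized.get(kmer, self.default_value)


def _windows(sequence: str, k: int) -> list[str]:
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


def count_kmers(dataset: EpitopeDataset, k: int) -> KmerCountTable:
    """Count every overlapping window of length k per class.

    A length-L peptide contributes max(L-k+1, 0) windows to its class;
    peptides shorter than k simply contribute nothing.
    """
    if k not in (2, 3):
        raise ValueError(f"k must be 2 (AAP) or 3 (AAT), got {k}")
    dataset.require_labeled()
    pos: Counter[str] = Counter()
    neg: Counter[str] = Counter()
    for p in dataset:
        target = pos if p.label == 1 else neg
        target.update(_windows(p.sequence, k))
    return KmerCountTable(
        k=k,
        counts_pos=dict(pos),
        counts_neg=dict(neg),
        total_pos=sum(pos.values()),
        total_neg=sum(neg.values()),
    )


def build_scale(counts: KmerCountTable, pseudocount: float = 1.0) -> KmerScale:
    """Turn a count table into a smoothed, normalized antigenicity scale.

    Raw values are computed over the union of k-mers observed in either
    class; k-mers never observed at all are handled at application time by
    ``default_value`` (0, neutral).
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    if counts.total_pos <= 0 or counts.total_neg <= 0:
        raise ValueError(
            "scale building needs k-mer windows in both classes "
            f"(totals: {counts.total_pos} pos, {counts.total_neg} neg)"
        )
    vocab = 20 ** counts.k
    denom_pos = counts.total_pos + pseudocount * vocab
    denom_neg = counts.total_neg + pseudocount * vocab
    observed = sorted(set(counts.counts_pos) | set(counts.counts_neg))
    raw = {
        m: math.log(
            (counts.counts_pos.get(m, 0) + pseudocount) / denom_pos
        )
        - math.log((counts.counts_neg.get(m, 0) + pseudocount) / denom_neg)
        for m in observed
    }
    values = np.array(list(raw.values()))
    lo, hi = float(values.min()), float(values.max())
    if hi - lo > 0:
        normalized = {m: 2.0 * (v - lo) / (hi - lo) - 1.0 for m, v in raw.items()}
    else:
        normalized = {m: 0.0 for m in raw}
    return KmerScale(
        k=counts.k,
        raw=raw,
        normalized=normalized,
        pseudocount=pseudocount,
        source=f"built from counts (k={counts.k}, "
        f"{counts.total_pos} pos / {counts.total_neg} neg windows)",
    )


def apply_scale(
    peptide: Peptide, scale: KmerScale, mode: str = "mean"
) -> float | np.ndarray:
    """Score a peptide against a scale.

    mode ``"mean"``: arithmetic mean of normalized values over all
    overlapping k-mers (unseen k-mers contribute ``default_value``); a
    peptide shorter than k scores 0 with a logged warning.

    mode ``"profile"``: a fixed 20**k vector where entry m is the fraction
    of the peptide's windows equal to m, multiplied by m's normalized value.
    """
    wins = _windows(peptide.sequence, scale.k)
    if mode == "mean":
        if not wins:
            logger.warning(
                "peptide %r shorter than k=%d; scale mean defaults to 0",
                peptide.id,
                scale.k,
            )
            return 0.0
        return float(
            sum(scale.normalized_value(w) for w in wins) / len(wins)
        )
    if mode == "profile":
        vec = np.zeros(20 ** scale.k)
        if not wins:
            logger.warning(
                "peptide %r shorter than k=%d; profile is all-zero",
                peptide.id,
                scale.k,
            )
            return vec
        kmers = all_kmers(scale.k)
        index = {m: i for i, m in enumerate(kmers)}
        counts = Counter(wins)
        n = len(wins)
        for m, c in counts.items():
            vec[index[m]] = (c / n) * scale.normalized_value(m)
        return vec
    raise ValueError(f"unknown mode {mode!r}; expected 'mean' or 'profile'")


def save_scale(scale: KmerScale, path: str | Path) -> None:
    """Persist a scale as TSV with metadata header lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#k={scale.k}\n")
        fh.write(f"#pseudocount={scale.pseudocount!r}\n")
        fh.write(f"#default={scale.default_value!r}\n")
        if scale.source:
            fh.write(f"#source={scale.source}\n")
        fh.write("kmer\traw\tnormalized\n")
        for m in sorted(scale.raw):
            fh.write(f"{m}\t{scale.raw[m]:.17g}\t{scale.normalized[m]:.17g}\n")


def load_scale(path: str | Path) -> KmerScale:
    """Load a scale saved by :func:`save_scale`; validates integrity."""
    path = Path(path)
    meta: dict[str, str] = {}
    raw: dict[str, float] = {}
    normalized: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key] = value
            body_start = i + 1
        else:
            break
    for key in ("k", "pseudocount", "default"):
        if key not in meta:
            raise ScaleFileError(f"{path}: missing metadata header '#{key}='")
    if body_start >= len(lines) or lines[body_start] != "kmer\traw\tnormalized":
        raise ScaleFileError(f"{path}: missing column header line")
    k = int(meta["k"])
    for line_no, line in enumerate(lines[body_start + 1 :], body_start + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ScaleFileError(f"{path} line {line_no}: expected 3 columns")
        m, raw_s, norm_s = parts
        if len(m) != k or set(m) - CANONICAL_SET:
            raise ScaleFileError(f"{path} line {line_no}: bad k-mer {m!r}")
        if m in raw:
            raise ScaleFileError(f"{path} line {line_no}: duplicate k-mer {m!r}")
        raw[m] = float(raw_s)
        normalized[m] = float(norm_s)
    return KmerScale(
        k=k,
        raw=raw,
        normalized=normalized,
        pseudocount=float(meta["pseudocount"]),
        default_value=float(meta["default"]),
        source=meta.get("source", f"loaded from {path}"),
    )
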