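"""Labeled synthetic peptide datasets with planted, documented structure.

The generator emulates the *shape* of public linear B-cell epitope
benchmarks — balanced fixed-length-20 sets and imbalanced variable-length
(5–25) sets — without any claim of distributional fidelity to curated
epitope databases. Every effect is planted explicitly and recoverable:

* **positional biases**: at a stated position, a stated residue is written
  with a class-specific probability (otherwise the background draws it), so
  per-position frequency differences are known targets for the enrichment
  analysis;
* **k-mer biases**: positives are rejection-resampled so the odds that a
  peptide *contains* a biased k-mer are multiplied by the stated factor
  (multiplier > 1 enriches, < 1 depletes), giving each biased k-mer a known
  expected sign in the antigenicity scale (:func:`planted_scale_oracle`);
* **embedding signal**: strength of a planted class direction for the
  informative mock embedding provider (0 = embeddings carry no label
  information).

Generation is fully seeded and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml

from epiboost._alphabet import CANONICAL_ALPHABET, CANONICAL_SET
from epiboost.embedding_providers import (
    EmbeddingProvider,
    InformativeMockProvider,
    MockEmbeddingProvider,
)
from epiboost.peptide_data import EpitopeDataset, Peptide

logger = logging.getLogger(__name__)

__all__ = [
    "PositionalBias",
    "GeneratorSpec",
    "generate",
    "planted_scale_oracle",
    "preset_bcpreds_like",
    "preset_ibce_like",
    "provider_for_spec",
]

_REJECTION_CAP = 1000


class PositionalBias(NamedTuple):
    """Write `residue` at `position` (0-based) with class-specific probability."""

    position: int
    residue: str
    prob_pos: float
    prob_neg: float


def _uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20)


@dataclass
class GeneratorSpec:
    """Full description of one synthetic dataset's study conditions."""

    n_pos: int
    n_neg: int
    min_length: int
    max_length: int
    background: np.ndarray = field(default_factory=_uniform_background)
    positional_biases: list[PositionalBias] = field(default_factory=list)
    kmer_biases: dict[str, float] = field(default_factory=dict)
    embedding_signal: float = 0.0
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be positive")
        if not (1 <= self.min_length <= self.max_length):
            raise ValueError(
                f"need 1 <= min_length <= max_length, got "
                f"[{self.min_length}, {self.max_length}]"
            )
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (20,):
            raise ValueError("background must be a 20-vector")
        if (self.background < 0).any() or abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must be nonnegative and sum to 1")
        for b in self.positional_biases:
            if not (0 <= b.position < self.min_length):
                raise ValueError(
                    f"positional bias at position {b.position} lies beyond the "
                    f"minimum length {self.min_length}"
                )
            if b.residue not in CANONICAL_SET:
                raise ValueError(f"bias residue {b.residue!r} is not canonical")
            for p in (b.prob_pos, b.prob_neg):
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"bias probability {p} outside [0,1]")
        for kmer, mult in self.kmer_biases.items():
            if set(kmer) - CANONICAL_SET or not 2 <= len(kmer) <= self.min_length:
                raise ValueError(f"invalid biased k-mer {kmer!r}")
            if mult <= 0:
                raise ValueError(f"k-mer odds multiplier must be > 0, got {mult}")
        if self.embedding_signal < 0:
            raise ValueError("embedding_signal must be >= 0")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "min_length": self.min_length,
            "max_length": self.max_length,
            "background": [float(x) for x in self.background],
            "positional_biases": [list(b) for b in self.positional_biases],
            "kmer_biases": dict(self.kmer_biases),
            "embedding_signal": self.embedding_signal,
            "seed": self.seed,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        d = dict(d)
        d["positional_biases"] = [
            PositionalBias(int(p), str(r), float(pp), float(pn))
            for p, r, pp, pn in d.get("positional_biases", [])
        ]
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _draw_sequence(
    rng: np.random.Generator, spec: GeneratorSpec, positive: bool
) -> str:
    if spec.min_length == spec.max_length:
        length = spec.min_length
    else:
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
    idx = rng.choice(20, size=length, p=spec.background)
    seq = [CANONICAL_ALPHABET[i] for i in idx]
    for b in spec.positional_biases:
        prob = b.prob_pos if positive else b.prob_neg
        if b.position < length and rng.random() < prob:
            seq[b.position] = b.residue
    return "".join(seq)


def _accept_positive(
    rng: np.random.Generator, seq: str, biases: dict[str, float]
) -> bool:
    """Indicator-tilt rejection: odds of containing each biased k-mer are
    multiplied by its factor. Envelope = product of the >1 multipliers."""
    weight = 1.0
    envelope = 1.0
    for kmer, mult in biases.items():
        if kmer in seq:
            weight *= mult
        if mult > 1.0:
            envelope *= mult
    return rng.random() < weight / envelope


def generate(spec: GeneratorSpec) -> EpitopeDataset:
    """Draw a labeled dataset per the spec; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    peptides: list[Peptide] = []
    for i in range(spec.n_pos):
        seq = None
        for _ in range(_REJECTION_CAP):
            candidate = _draw_sequence(rng, spec, positive=True)
            if not spec.kmer_biases or _accept_positive(
                rng, candidate, spec.kmer_biases
            ):
                seq = candidate
                break
        if seq is None:
            logger.warning(
                "rejection cap (%d) hit for positive %d; keeping last draw",
                _REJECTION_CAP,
                i,
            )
            seq = candidate
        peptides.append(Peptide(id=f"pos_{i:05d}", sequence=seq, label=1))
    for i in range(spec.n_neg):
        peptides.append(
            Peptide(
                id=f"neg_{i:05d}",
                sequence=_draw_sequence(rng, spec, positive=False),
                label=0,
            )
        )
    return EpitopeDataset(
        name=spec.name,
        peptides=peptides,
        provenance=f"synthetic (seed={spec.seed})",
    )


def planted_scale_oracle(spec: GeneratorSpec) -> dict[str, int]:
    """Expected sign of each biased k-mer's raw antigenicity log-ratio."""
    return {
        kmer: (1 if mult > 1.0 else -1)
        for kmer, mult in spec.kmer_biases.items()
        if mult != 1.0
    }


def preset_bcpreds_like(
    n_pos: int = 701, n_neg: int = 701, seed: int = 0
) -> GeneratorSpec:
    """Balanced fixed-length-20 set with strong planted effects.

    Echoes (does not reproduce) the structure of fixed-length epitope
    benchmarks: proline strongly enriched at several positions in
    positives, threonine/glycine/aspartate moderately enriched, and
    leucine/isoleucine/phenylalanine depleted; dipeptide and tripeptide
    odds biases give the antigenicity scales known-sign targets.
    """
    return GeneratorSpec(
        n_pos=n_pos,
        n_neg=n_neg,
        min_length=20,
        max_length=20,
        positional_biases=[
            PositionalBias(2, "P", 0.50, 0.02),
            PositionalBias(5, "P", 0.50, 0.02),
            PositionalBias(9, "P", 0.50, 0.02),
            PositionalBias(13, "P", 0.50, 0.02),
            PositionalBias(17, "P", 0.50, 0.02),
            PositionalBias(4, "T", 0.45, 0.03),
            PositionalBias(8, "G", 0.45, 0.03),
            PositionalBias(12, "D", 0.45, 0.03),
            PositionalBias(1, "L", 0.01, 0.45),
            PositionalBias(10, "L", 0.01, 0.45),
            PositionalBias(6, "I", 0.01, 0.40),
            PositionalBias(15, "F", 0.01, 0.40),
        ],
        kmer_biases={"PG": 4.0, "TG": 4.0, "LL": 0.15, "PGT": 10.0},
        embedding_signal=0.0,
        seed=seed,
        name="bcpreds_like",
    )


def preset_ibce_like(scale: float = 1.0, seed: int = 0) -> GeneratorSpec:
    """Imbalanced variable-length (5–25) set, ~0.447 positive fraction.

    Positional biases are omitted (no shared alignment across lengths);
    mild k-mer odds biases carry the class signal.
    """
    return GeneratorSpec(
        n_pos=max(1, int(round(4440 * scale))),
        n_neg=max(1, int(round(5485 * scale))),
        min_length=5,
        max_length=25,
        kmer_biases={"PG": 2.0, "LL": 0.5},
        embedding_signal=0.0,
        seed=seed,
        name="ibce_like",
    )


def provider_for_spec(
    dataset: EpitopeDataset,
    spec: GeneratorSpec,
    dim: int = 64,
    pooling: str = "cls",
    seed: int | None = None,
) -> EmbeddingProvider:
    """Mock embedding provider matching the spec's planted embedding signal."""
    seed = spec.seed if seed is None else seed
    if spec.embedding_signal > 0:
        return InformativeMockProvider(
            seed=seed,
            dim=dim,
            labels_by_sequence={p.sequence: p.label for p in dataset},
            strength=min(1.0, spec.embedding_signal),
            pooling=pooling,
        )
    return MockEmbeddingProvider(seed=seed, dim=dim, pooling=pooling)
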