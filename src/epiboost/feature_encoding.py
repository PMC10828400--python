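"""Fixed-dimension peptide feature vectors: AAC ⊕ AAP ⊕ AAT ⊕ embedding.

A variable-length peptide maps to a constant-width vector: the 20-entry
amino acid composition (per-residue frequency, alphabetical order), the
dipeptide and tripeptide antigenicity blocks (scalar window means by
default, full 400-/8000-dim frequency-weighted profiles optionally), and an
optional pooled language-model embedding. The block order and feature names
are fixed and recorded with any trained model so schemas can be verified.

Tree ensembles are scale-invariant, so no cross-block standardization is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from epiboost._alphabet import AA_INDEX, CANONICAL_ALPHABET, all_kmers
from epiboost.antigen_scales import KmerScale, apply_scale
from epiboost.embedding_providers import EmbeddingProvider
from epiboost.peptide_data import EpitopeDataset, Peptide

__all__ = [
    "EncoderConfig",
    "FeatureVector",
    "FeatureMatrix",
    "compute_aac",
    "encode_peptide",
    "encode_dataset",
    "feature_names",
]

_BLOCK_MODES = ("mean", "profile", "off")


@dataclass(frozen=True)
class EncoderConfig:
    """Which feature blocks to emit and how.

    aap_mode / aat_mode : "mean" (one scalar), "profile" (20**k vector), "off".
    embedding : "on" | "off"; pooling only meaningful when on.
    embedding_dim : width the provider must match (default 768, a typical
        base-size transformer hidden width).
    """

    aap_mode: str = "mean"
    aat_mode: str = "mean"
    embedding: str = "on"
    pooling: str = "cls"
    embedding_dim: int = 768

    def __post_init__(self) -> None:
        if self.aap_mode not in _BLOCK_MODES:
            raise ValueError(f"aap_mode must be one of {_BLOCK_MODES}")
        if self.aat_mode not in _BLOCK_MODES:
            raise ValueError(f"aat_mode must be one of {_BLOCK_MODES}")
        if self.embedding not in ("on", "off"):
            raise ValueError("embedding must be 'on' or 'off'")
        if self.pooling not in ("cls", "avg"):
            raise ValueError("pooling must be 'cls' or 'avg'")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")

    def to_dict(self) -> dict:
        return {
            "aap_mode": self.aap_mode,
            "aat_mode": self.aat_mode,
            "embedding": self.embedding,
            "pooling": self.pooling,
            "embedding_dim": self.embedding_dim,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        return cls(**d)


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")


@dataclass
class FeatureMatrix:
    """Row-aligned features, labels and peptide ids for a whole dataset."""

    values: np.ndarray  # (n, d)
    names: list[str]
    ids: list[str]
    labels: list[int | None]

    def labels_array(self) -> np.ndarray:
        if any(l is None for l in self.labels):
            raise ValueError("feature matrix contains unlabeled peptides")
        return np.array(self.labels, dtype=int)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "label", ["" if l is None else l for l in self.labels])
        df.insert(0, "id", self.ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        if list(df.columns[:2]) != ["id", "label"]:
            raise ValueError(f"{path}: expected leading columns id, label")
        labels = [
            None if pd.isna(l) else int(l) for l in df["label"]
        ]
        names = list(df.columns[2:])
        return cls(
            values=df[names].to_numpy(dtype=float),
            names=names,
            ids=[str(i) for i in df["id"]],
            labels=labels,
        )


def compute_aac(peptide: Peptide) -> np.ndarray:
    """Amino acid composition: per-residue frequency, order ACDEFGHIKLMNPQRSTVWY."""
    vec = np.zeros(20)
    for res in peptide.sequence:
        vec[AA_INDEX[res]] += 1
    return vec / len(peptide.sequence)


def _block_names(prefix: str, mode: str, k: int) -> list[str]:
    if mode == "off":
        return []
    if mode == "mean":
        return [prefix]
    return [f"{prefix}_{m}" for m in all_kmers(k)]


def feature_names(config: EncoderConfig) -> list[str]:
    """The fixed, ordered feature-name list an EncoderConfig produces."""
    names = [f"AAC_{aa}" for aa in CANONICAL_ALPHABET]
    names += _block_names("AAP", config.aap_mode, 2)
    names += _block_names("AAT", config.aat_mode, 3)
    if config.embedding == "on":
        names += [f"EMB_{i}" for i in range(config.embedding_dim)]
    return names


def _scale_block(
    peptide: Peptide, scale: KmerScale | None, mode: str, expect_k: int, which: str
) -> np.ndarray:
    if mode == "off":
        return np.empty(0)
    if scale is None:
        raise ValueError(f"{which} scale required when {which.lower()}_mode != 'off'")
    if scale.k != expect_k:
        raise ValueError(f"{which} scale must have k={expect_k}, got k={scale.k}")
    out = apply_scale(peptide, scale, mode=mode)
    return np.atleast_1d(np.asarray(out, dtype=float))


def encode_peptide(
    peptide: Peptide,
    aap: KmerScale | None,
    aat: KmerScale | None,
    provider: EmbeddingProvider | None,
    config: EncoderConfig,
) -> FeatureVector:
    """Encode one peptide as the fixed-order concatenation of feature blocks."""
    blocks = [compute_aac(peptide)]
    blocks.append(_scale_block(peptide, aap, config.aap_mode, 2, "AAP"))
    blocks.append(_scale_block(peptide, aat, config.aat_mode, 3, "AAT"))
    if config.embedding == "on":
        if provider is None:
            raise ValueError("embedding is on but no provider was given")
        emb = np.asarray(provider.embed(peptide), dtype=float)
        if emb.shape != (config.embedding_dim,):
            raise ValueError(
                f"provider returned dim {emb.shape} for peptide {peptide.id!r}; "
                f"encoder expects ({config.embedding_dim},)"
            )
        blocks.append(emb)
    elif provider is not None:
        raise ValueError("a provider was given but embedding is off")
    return FeatureVector(values=np.concatenate(blocks), names=feature_names(config))


def encode_dataset(
    dataset: EpitopeDataset,
    aap: KmerScale | None,
    aat: KmerScale | None,
    provider: EmbeddingProvider | None,
    config: EncoderConfig,
) -> FeatureMatrix:
    """Encode a whole dataset; row order follows dataset order."""
    if len(dataset) == 0:
        raise ValueError("cannot encode an empty dataset")
    rows = []
    names: list[str] | None = None
    for p in dataset:
        try:
            fv = encode_peptide(p, aap, aat, provider, config)
        except Exception as exc:
            raise type(exc)(f"while encoding peptide {p.id!r}: {exc}") from exc
        rows.append(fv.values)
        names = fv.names
    assert names is not None
    return FeatureMatrix(
        values=np.vstack(rows),
        names=names,
        ids=dataset.ids(),
        labels=[p.label for p in dataset],
    )
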