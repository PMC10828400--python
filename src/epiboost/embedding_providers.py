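"""Per-peptide embedding vectors behind a uniform provider contract.

The feature encoder never knows where an embedding came from: a provider
exposes ``dim``, ``pooling`` and ``embed(peptide) -> vector of dim reals``,
deterministic for a given sequence and pooling. Three providers ship:

* :class:`MockEmbeddingProvider` — seeded pseudo-random vectors keyed on the
  sequence (cls pooling) or on per-(residue, position) hashes averaged over
  the chain (avg pooling). Class-uninformative by construction, so
  discrimination tests on synthetic data isolate the sequence features.
* :class:`InformativeMockProvider` — the mock plus a planted class
  direction, for end-to-end tests where the embedding should carry signal.
* :class:`PrecomputedEmbeddingProvider` — verbatim lookup of vectors from a
  TSV (id, EMB_0..EMB_{d-1}), for embeddings computed offline.
* :class:`PretrainedTransformerProvider` — optional adapter extracting the
  first-token (CLS) or residue-averaged vector from a local pretrained
  protein language model; requires the optional ``transformers``/``torch``
  dependencies and is never needed by the test suite.
"""

from __future__ import annotations

import hashlib
from abc import ABC, abstractmethod
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from epiboost.peptide_data import Peptide

__all__ = [
    "EmbeddingProvider",
    "EmbeddingLookupError",
    "MockEmbeddingProvider",
    "InformativeMockProvider",
    "PrecomputedEmbeddingProvider",
    "PretrainedTransformerProvider",
    "write_embedding_tsv",
]

POOLING_MODES = ("cls", "avg")


class EmbeddingLookupError(KeyError):
    """A requested peptide has no stored embedding."""


class EmbeddingProvider(ABC):
    """Contract: embed(peptide) returns exactly ``dim`` reals, deterministically."""

    dim: int
    pooling: str

    @abstractmethod
    def embed(self, peptide: Peptide) -> np.ndarray:
        """Return the pooled embedding vector for one peptide."""

    def embed_many(self, peptides) -> np.ndarray:
        return np.vstack([self.embed(p) for p in peptides])


def _hash_rng(*key_parts) -> np.random.Generator:
    digest = hashlib.blake2b(
        "|".join(str(p) for p in key_parts).encode(), digest_size=8
    ).digest()
    return np.random.default_rng(int.from_bytes(digest, "big"))


class MockEmbeddingProvider(EmbeddingProvider):
    """Deterministic seeded stand-in for a protein language model.

    cls pooling: one uniform[-1,1] vector from a hash of the full sequence.
    avg pooling: the mean of per-(residue, position) hash vectors, so a
    length-1 peptide's avg embedding equals its single residue's vector.
    """

    def __init__(self, seed: int, dim: int, pooling: str = "cls"):
        if dim < 1:
            raise ValueError(f"dim must be >= 1, got {dim}")
        if pooling not in POOLING_MODES:
            raise ValueError(f"pooling must be one of {POOLING_MODES}, got {pooling!r}")
        self.seed = seed
        self.dim = dim
        self.pooling = pooling

    def _residue_vector(self, residue: str, position: int) -> np.ndarray:
        rng = _hash_rng("mock-res", self.seed, residue, position)
        return rng.uniform(-1.0, 1.0, self.dim)

    def embed(self, peptide: Peptide) -> np.ndarray:
        if self.pooling == "cls":
            rng = _hash_rng("mock-cls", self.seed, peptide.sequence)
            return rng.uniform(-1.0, 1.0, self.dim)
        vecs = [
            self._residue_vector(res, i) for i, res in enumerate(peptide.sequence)
        ]
        return np.mean(vecs, axis=0)


class InformativeMockProvider(EmbeddingProvider):
    """Mock embeddings mixed with a planted class direction.

    ``strength`` in [0, 1] convexly blends the uninformative mock vector
    with +/- a fixed seeded direction according to the peptide's class,
    looked up by sequence. Sequences absent from the lookup get the plain
    mock vector. Output stays in [-1, 1].
    """

    def __init__(
        self,
        seed: int,
        dim: int,
        labels_by_sequence: Mapping[str, int],
        strength: float,
        pooling: str = "cls",
    ):
        if not (0.0 <= strength <= 1.0):
            raise ValueError(f"strength must be in [0,1], got {strength}")
        self._base = MockEmbeddingProvider(seed=seed, dim=dim, pooling=pooling)
        self.dim = dim
        self.pooling = pooling
        self.strength = strength
        self._labels = dict(labels_by_sequence)
        self._direction = _hash_rng("mock-dir", seed).uniform(-1.0, 1.0, dim)

    def embed(self, peptide: Peptide) -> np.ndarray:
        base = self._base.embed(peptide)
        label = self._labels.get(peptide.sequence)
        if label is None or self.strength == 0.0:
            return base
        sign = 1.0 if label == 1 else -1.0
        return (1.0 - self.strength) * base + self.strength * sign * self._direction


class PrecomputedEmbeddingProvider(EmbeddingProvider):
    """Verbatim lookup of per-peptide vectors keyed by peptide id."""

    def __init__(self, vectors: Mapping[str, np.ndarray], pooling: str = "cls"):
        if not vectors:
            raise ValueError("empty embedding table")
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"ragged embedding table: dims {sorted(dims)}")
        self.dim = dims.pop()
        self.pooling = pooling
        self._vectors = {k: np.asarray(v, dtype=float) for k, v in vectors.items()}

    @classmethod
    def from_tsv(cls, path: str | Path, pooling: str = "cls") -> "PrecomputedEmbeddingProvider":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        if "id" not in df.columns:
            raise ValueError(f"{path}: missing 'id' column")
        value_cols = [c for c in df.columns if c != "id"]
        if not value_cols:
            raise ValueError(f"{path}: no embedding columns")
        if df[value_cols].isna().any().any():
            raise ValueError(f"{path}: ragged or non-numeric embedding rows")
        vectors = {
            str(row["id"]): row[value_cols].to_numpy(dtype=float)
            for _, row in df.iterrows()
        }
        return cls(vectors, pooling=pooling)

    def embed(self, peptide: Peptide) -> np.ndarray:
        try:
            return self._vectors[peptide.id]
        except KeyError:
            raise EmbeddingLookupError(
                f"no precomputed embedding for peptide id {peptide.id!r}"
            ) from None


def write_embedding_tsv(
    vectors: Mapping[str, np.ndarray], path: str | Path
) -> None:
    """Write an id -> vector table in the provider's TSV format."""
    dims = {len(v) for v in vectors.values()}
    if len(dims) != 1:
        raise ValueError(f"ragged embedding table: dims {sorted(dims)}")
    dim = dims.pop()
    df = pd.DataFrame(
        [[k, *np.asarray(v, dtype=float)] for k, v in vectors.items()],
        columns=["id", *[f"EMB_{i}" for i in range(dim)]],
    )
    df.to_csv(path, sep="\t", index=False)


class PretrainedTransformerProvider(EmbeddingProvider):
    """Adapter for a locally available pretrained protein language model.

    ``cls`` pooling takes the first-token vector of the chosen encoder
    layer; ``avg`` averages residue-token vectors excluding special tokens.
    The layer defaults to the final encoder layer. Requires the optional
    ``transformers`` and ``torch`` packages and a local checkpoint; when
    unavailable, construction fails with an actionable error and the rest
    of the pipeline remains usable with the mock or precomputed providers.
    """

    def __init__(
        self,
        model_locator: str,
        pooling: str = "cls",
        layer: int = -1,
    ):
        if pooling not in POOLING_MODES:
            raise ValueError(f"pooling must be one of {POOLING_MODES}, got {pooling!r}")
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:
            raise RuntimeError(
                "PretrainedTransformerProvider needs the optional 'transformers' "
                "and 'torch' dependencies (pip install epiboost[bert]); use the "
                "mock or precomputed provider otherwise"
            ) from exc
        self.pooling = pooling
        self.layer = layer
        self._tokenizer = AutoTokenizer.from_pretrained(model_locator)
        self._model = AutoModel.from_pretrained(
            model_locator, output_hidden_states=True
        )
        self._model.eval()
        self.dim = int(self._model.config.hidden_size)

    def embed(self, peptide: Peptide) -> np.ndarray:
        import torch

        # Protein LMs conventionally take space-separated residues.
        tokens = self._tokenizer(
            " ".join(peptide.sequence), return_tensors="pt"
        )
        with torch.no_grad():
            out = self._model(**tokens)
        hidden = out.hidden_states[self.layer][0]  # (n_tokens, dim)
        if self.pooling == "cls":
            vec = hidden[0]
        else:
            special = self._tokenizer.get_special_tokens_mask(
                tokens["input_ids"][0].tolist(), already_has_special_tokens=True
            )
            keep = [i for i, s in enumerate(special) if not s]
            vec = hidden[keep].mean(dim=0)
        return vec.numpy().astype(float)
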