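import numpy as np
import pytest

from epiboost.peptide_data import EpitopeDataset, Peptide


def make_dataset(sequences_labels, name="fixture"):
    """Build a dataset from (sequence, label) pairs with generated ids."""
    peptides = [
        Peptide(id=f"p{i}", sequence=seq, label=label)
        for i, (seq, label) in enumerate(sequences_labels)
    ]
    return EpitopeDataset(name=name, peptides=peptides)


def random_dataset(rng, n_pos, n_neg, min_len=8, max_len=12, name="random"):
    """Unstructured random peptides: labels carry no sequence information."""
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    peptides = []
    for i in range(n_pos + n_neg):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(alphabet, size=length))
        peptides.append(
            Peptide(id=f"r{i}", sequence=seq, label=1 if i < n_pos else 0)
        )
    return EpitopeDataset(name=name, peptides=peptides)


@pytest.fixture
def tiny_dataset():
    return make_dataset(
        [("ACDKLM", 1), ("WYTTGG", 0), ("PPGTAC", 1), ("LLIVFA", 0)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240130)
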