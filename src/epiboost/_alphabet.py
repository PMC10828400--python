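"""The 20-letter canonical amino-acid alphabet and k-mer enumeration."""

from functools import lru_cache
from itertools import product

CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
CANONICAL_SET = frozenset(CANONICAL_ALPHABET)

# Ambiguity / non-standard codes that may appear in real protein data but
# are rejected (or dropped, by policy) before any k-mer math.
NON_CANONICAL_CODES = frozenset("BJOUXZ")

AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_ALPHABET)}


@lru_cache(maxsize=None)
def all_kmers(k: int) -> tuple[str, ...]:
    """All 20**k k-mers in lexicographic order over the canonical alphabet."""
    return tuple("".join(p) for p in product(CANONICAL_ALPHABET, repeat=k))
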