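"""Fixed-length k-mer tokenization of RNA sequences.

A sequence of length n yields n-k+1 overlapping (stride-1) k-mers, each
mapped to an integer index by lexicographic enumeration over A<C<G<U.
Token sequences are right-padded with a dedicated pad index (= 4^k, just
past the k-mer range) to the model window, or truncated at the window
keeping the 5' prefix.  The default window is 224 tokens with a learned
16-dimensional embedding per token.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import SequenceRecord

RNA_ORDER = "ACGU"
DEFAULT_MAX_LEN = 224
DEFAULT_EMBEDDING_DIM = 16

__all__ = [
    "KmerVocabulary",
    "TokenSequence",
    "EmbeddingSpec",
    "build_vocab",
    "tokenize",
    "detokenize",
    "tokenize_dataset",
]


@dataclass(frozen=True)
class KmerVocabulary:
    k: int
    token_to_index: dict[str, int]
    pad_index: int

    @property
    def size(self) -> int:
        """Embedding-table size: all 4^k k-mers plus the pad token."""
        return len(self.token_to_index) + 1

    def index_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_index.items()}


@dataclass(frozen=True)
class TokenSequence:
    """Integer-coded k-mers, padded/truncated to a fixed window."""

    indices: np.ndarray
    n_real: int

    def __post_init__(self):
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.intp))


@dataclass(frozen=True)
class EmbeddingSpec:
    vocab_size: int
    dim: int = DEFAULT_EMBEDDING_DIM

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("embedding dimension must be >= 1")


def build_vocab(k: int) -> KmerVocabulary:
    """Enumerate all 4^k k-mers in lexicographic A<C<G<U order."""
    if not 1 <= k <= 4:
        raise ValueError(f"k={k} outside supported range [1, 4]")
    tokens: dict[str, int] = {}

    def extend(prefix: str):
        if len(prefix) == k:
            tokens[prefix] = len(tokens)
            return
        for base in RNA_ORDER:
            extend(prefix + base)

    extend("")
    return KmerVocabulary(k=k, token_to_index=tokens, pad_index=len(tokens))


def tokenize(
    record: SequenceRecord | str,
    vocab: KmerVocabulary,
    max_len: int = DEFAULT_MAX_LEN,
) -> TokenSequence:
    """Map a normalized sequence to its padded k-mer index sequence."""
    seq = record if isinstance(record, str) else record.residues
    rid = "?" if isinstance(record, str) else record.id
    if len(seq) < vocab.k:
        raise ValueError(f"record {rid!r}: length {len(seq)} shorter than k={vocab.k}")
    n_real = min(len(seq) - vocab.k + 1, max_len)
    indices = np.full(max_len, vocab.pad_index, dtype=np.intp)
    lut = vocab.token_to_index
    for pos in range(n_real):
        indices[pos] = lut[seq[pos:pos + vocab.k]]
    return TokenSequence(indices=indices, n_real=n_real)


def detokenize(tokens: TokenSequence, vocab: KmerVocabulary) -> str:
    """Reconstruct the sequence prefix covered by the non-pad tokens.

    Overlapping stride-1 k-mers are invertible: the first token
    contributes k characters, every later one its final character.
    """
    rev = vocab.index_to_token()
    real = tokens.indices[: tokens.n_real]
    if len(real) == 0:
        return ""
    parts = [rev[int(real[0])]]
    parts.extend(rev[int(i)][-1] for i in real[1:])
    return "".join(parts)


def tokenize_dataset(records, vocab: KmerVocabulary, max_len: int = DEFAULT_MAX_LEN) -> np.ndarray:
    """Stack token index rows for a collection of records -> (N, max_len)."""
    return np.stack([tokenize(rec, vocab, max_len).indices for rec in records])
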