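"""Overlapping k-mer tokenization for DNA sequences.

A sequence is split into overlapping k-mers (default k=6) at a fixed
stride — stride 3 for CDS classification (frame-aligned dicodon tokens),
stride 1 for TIS classification — then mapped to integer ids with [CLS]
prepended and [EOS] appended, right-padded with [PAD] to a fixed length.
k-mers containing any base outside {A,C,G,T} map to [UNK].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

PAD, UNK, CLS, EOS = "[PAD]", "[UNK]", "[CLS]", "[EOS]"
SPECIAL_TOKENS = (PAD, UNK, CLS, EOS)

#: Fixed model input lengths: 55 stride-1 6-mers of a 60-nt window plus the
#: two special tokens give 57; CDS inputs are padded to 512.
TIS_MAX_LEN = 57
CDS_MAX_LEN = 512
CDS_MAX_SEQ = 510
TIS_WINDOW = 60


@dataclass(frozen=True)
class Vocabulary:
    """Dense bijection between k-mers plus specials and integer ids."""

    k: int = 6
    token_to_id: dict = field(default_factory=dict)
    id_to_token: tuple = ()

    @classmethod
    def build(cls, k: int = 6) -> "Vocabulary":
        tokens = list(SPECIAL_TOKENS) + [
            "".join(p) for p in product("ACGT", repeat=k)]
        return cls(k=k,
                   token_to_id={t: i for i, t in enumerate(tokens)},
                   id_to_token=tuple(tokens))

    def __len__(self) -> int:
        return len(self.id_to_token)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def cls_id(self) -> int:
        return self.token_to_id[CLS]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.id_to_token) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        tokens = Path(path).read_text().splitlines()
        k = len(tokens[-1])
        return cls(k=k, token_to_id={t: i for i, t in enumerate(tokens)},
                   id_to_token=tuple(tokens))


@dataclass(frozen=True)
class TokenSequence:
    """Token ids with a padding mask; ids[0] is [CLS], last real id [EOS]."""

    ids: np.ndarray
    mask: np.ndarray

    @property
    def n_real(self) -> int:
        return int(self.mask.sum())


def kmerize(seq: str, k: int = 6, stride: int = 1) -> list[str]:
    """Split ``seq`` into overlapping k-mers: window i starts at i*stride.

    Returns ``floor((len(seq)-k)/stride) + 1`` substrings.
    """
    if k < 1 or stride < 1:
        raise ValueError("k and stride must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    n = (len(seq) - k) // stride + 1
    return [seq[i * stride:i * stride + k] for i in range(n)]


def encode(kmers: list[str], vocab: Vocabulary,
           max_len: int) -> TokenSequence:
    """Map k-mers to a fixed-length id sequence with specials and padding."""
    n_real = len(kmers) + 2
    if n_real > max_len:
        raise ValueError(
            f"{len(kmers)} k-mers + 2 specials exceed max_len={max_len}; "
            "truncate the sequence upstream")
    t2i = vocab.token_to_id
    unk = vocab.unk_id
    ids = np.full(max_len, vocab.pad_id, dtype=np.int64)
    ids[0] = vocab.cls_id
    for j, km in enumerate(kmers, start=1):
        ids[j] = t2i.get(km, unk)
    ids[n_real - 1] = vocab.eos_id
    mask = np.zeros(max_len, dtype=np.int64)
    mask[:n_real] = 1
    return TokenSequence(ids=ids, mask=mask)


def decode(tokens: TokenSequence, vocab: Vocabulary, stride: int = 1) -> str:
    """Reconstruct the nucleotide sequence from a stride-``stride`` encoding.

    Inverse of ``encode(kmerize(seq, k, stride), ...)`` whenever the stride
    tiles the sequence without gaps (stride <= k) and no k-mer mapped to
    [UNK].
    """
    kmers = [vocab.id_to_token[i]
             for i in tokens.ids[1:tokens.n_real - 1]]
    if not kmers:
        return ""
    out = kmers[0]
    for km in kmers[1:]:
        out += km[-stride:]
    return out


def encode_sequence(seq: str, vocab: Vocabulary, stride: int,
                    max_len: int) -> TokenSequence:
    """Convenience: kmerize then encode in one step."""
    return encode(kmerize(seq, vocab.k, stride), vocab, max_len)
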