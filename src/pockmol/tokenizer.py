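"""Vocabulary and integer-sequence handling for molecule tokens.

Molecules move through three representations: SMILES strings, chemical
token lists (see :mod:`pockmol.grammar`) and integer index sequences fed
to the decoder network. There is no start-of-sequence token — the graph
embedding occupies the first decoder input slot — so the only special
tokens are ``<pad>`` (index 0) and ``<eos>`` (index 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import grammar
from .grammar import GrammarError, canonical_smiles

PAD, EOS = "<pad>", "<eos>"
PAD_IDX, EOS_IDX = 0, 1

#: Grammar revision recorded in every artifact that stores tokens, so a
#: vocabulary file can be matched to the token inventory that produced it.
GRAMMAR_VERSION = "pockmol-grammar-1"

#: Default cap on sequence length (tokens incl. <eos>); covers drug-like
#: molecules comfortably.
MAX_LEN = 140


def smiles_to_tokens(smiles: str) -> list[str]:
    """Tokenize a SMILES string into grammar tokens (round-trip safe)."""
    return grammar.encode(smiles)


def tokens_to_smiles(tokens: list[str]) -> str:
    return grammar.decode(tokens)


@dataclass(frozen=True)
class Vocabulary:
    """Bijection between tokens and indices; specials pinned at 0 and 1."""

    token_to_index: dict[str, int]

    def __post_init__(self) -> None:
        t2i = self.token_to_index
        if t2i.get(PAD) != PAD_IDX or t2i.get(EOS) != EOS_IDX:
            raise ValueError("vocabulary must map <pad> to 0 and <eos> to 1")
        if len(set(t2i.values())) != len(t2i) or len(t2i) < 3:
            raise ValueError("vocabulary must be a bijection with >= 1 chemical token")

    @property
    def size(self) -> int:
        return len(self.token_to_index)

    @property
    def index_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_index.items()}

    @property
    def chemical_tokens(self) -> list[str]:
        return [t for t in self.token_to_index if t not in (PAD, EOS)]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"grammar": GRAMMAR_VERSION, "tokens": self.token_to_index}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(payload["tokens"] if "tokens" in payload else payload)


@dataclass
class TokenSequence:
    """An index sequence; if ``terminated`` the last non-pad index is <eos>."""

    indices: list[int]
    terminated: bool = True

    def __post_init__(self) -> None:
        seen_pad = False
        for idx in self.indices:
            if idx == PAD_IDX:
                seen_pad = True
            elif seen_pad:
                raise ValueError("<pad> may not precede a non-pad token")
        if self.terminated:
            nonpad = [i for i in self.indices if i != PAD_IDX]
            if not nonpad or nonpad[-1] != EOS_IDX:
                raise ValueError("terminated sequence must end with <eos>")

    @property
    def length(self) -> int:
        """Number of non-pad tokens, including <eos> when present."""
        return sum(1 for i in self.indices if i != PAD_IDX)


def build_vocab(corpus: list[str]) -> Vocabulary:
    """Vocabulary over all tokens appearing in a corpus of SMILES strings.

    Deterministic: chemical tokens are sorted, specials pinned first, so
    the same corpus (as a multiset, in any order) yields the same mapping.
    """
    if not corpus:
        raise ValueError("empty corpus")
    tokens: set[str] = set()
    for smi in corpus:
        tokens.update(smiles_to_tokens(smi))
    t2i = {PAD: PAD_IDX, EOS: EOS_IDX}
    for i, tok in enumerate(sorted(tokens)):
        t2i[tok] = i + 2
    return Vocabulary(t2i)


def encode(smiles: str, vocab: Vocabulary) -> TokenSequence:
    """SMILES -> terminated index sequence (chemical tokens + <eos>)."""
    toks = smiles_to_tokens(smiles)
    missing = [t for t in toks if t not in vocab.token_to_index]
    if missing:
        raise KeyError(f"tokens not in vocabulary: {sorted(set(missing))}")
    return TokenSequence([vocab.token_to_index[t] for t in toks] + [EOS_IDX])


def decode(seq: TokenSequence | list[int], vocab: Vocabulary) -> str:
    """Index sequence -> canonical SMILES; '' for an empty derivation.

    Total over in-range chemical indices: any sequence (random included)
    decodes to a valid molecule — the grammar's robustness guarantee.
    """
    indices = seq.indices if isinstance(seq, TokenSequence) else list(seq)
    i2t = vocab.index_to_token
    toks = []
    for idx in indices:
        if idx in (PAD_IDX, EOS_IDX):
            break
        if idx not in i2t:
            raise KeyError(f"index {idx} out of vocabulary range")
        toks.append(i2t[idx])
    return tokens_to_smiles(toks)


def pad_batch(seqs: list[TokenSequence], max_len: int = MAX_LEN,
              truncate: bool = False):
    """Right-pad sequences into an index matrix.

    Returns ``(matrix B×max_len, lengths B)``; lengths count non-pad
    tokens including <eos>. Overlong sequences raise by default
    (training); with ``truncate=True`` they are clipped and the clipped
    row is marked in the returned ``truncated`` boolean vector.
    """
    if not seqs:
        raise ValueError("empty batch")
    mat = np.full((len(seqs), max_len), PAD_IDX, dtype=np.int64)
    lengths = np.zeros(len(seqs), dtype=np.int64)
    truncated = np.zeros(len(seqs), dtype=bool)
    for r, seq in enumerate(seqs):
        idx = [i for i in seq.indices if i != PAD_IDX]
        if len(idx) > max_len:
            if not truncate:
                raise ValueError(f"sequence of length {len(idx)} exceeds max_len={max_len}")
            idx = idx[:max_len]
            truncated[r] = True
        mat[r, :len(idx)] = idx
        lengths[r] = len(idx)
    return mat, lengths, truncated


def unpad(mat: np.ndarray, lengths: np.ndarray) -> list[TokenSequence]:
    out = []
    for row, n in zip(mat, lengths):
        idx = [int(v) for v in row[:n]]
        out.append(TokenSequence(idx, terminated=bool(idx and idx[-1] == EOS_IDX)))
    return out
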