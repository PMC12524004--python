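"""SMILES tokenization and fixed-width encoding.

Molecules are represented as single-character token sequences over a
33-symbol alphabet.  The two-letter halogens are substituted by single
characters (``Cl`` -> ``D``, ``Br`` -> ``E``) so that every token is one
character; a begin-of-sequence symbol ``$`` is prepended, an
end-of-sequence symbol ``~`` appended, and sequences are right-padded
with ``€`` to a fixed width ``L = max_raw_len + 2``.  Each position is
also available as a one-hot row vector of width ``s`` (the alphabet
size), giving the ``L x s`` binary matrix consumed by the decoder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TokenVocabulary",
    "EncodedSmiles",
    "build_default_vocabulary",
    "tokenize",
    "pad_encode",
    "decode",
    "encode_smiles",
    "DEFAULT_MAX_RAW_LEN",
]

#: default maximum raw SMILES length; encoded width is this plus BoS and EoS
DEFAULT_MAX_RAW_LEN = 95

# Single-character stand-ins for the two-letter halogens, applied before
# character-level splitting.
DEFAULT_SUBSTITUTIONS = {"Cl": "D", "Br": "E"}

# 33 symbols: 3 specials + 2 halogen substitutes + 8 organic-subset atoms +
# 4 aromatic atoms + 9 ring-closure digits + 7 structural characters.
_DEFAULT_SYMBOLS = (
    ["$", "~", "€"]
    + ["D", "E"]
    + ["C", "N", "O", "P", "S", "F", "I", "H"]
    + ["c", "n", "o", "s"]
    + [str(d) for d in range(1, 10)]
    + ["(", ")", "[", "]", "=", "#", "%"]
)


class VocabularyError(ValueError):
    """A character outside the vocabulary was encountered."""


@dataclass(frozen=True)
class TokenVocabulary:
    """An ordered single-character alphabet with delimiter roles.

    Parameters
    ----------
    symbols
        Ordered distinct single characters; index in this sequence is the
        integer token id.
    bos, eos, pad
        Distinguished delimiter symbols, all members of ``symbols``.
    substitutions
        Multi-character substrings replaced by single characters before
        tokenization (and reversed on decoding).
    """

    symbols: tuple[str, ...]
    bos: str = "$"
    eos: str = "~"
    pad: str = "€"
    substitutions: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUTIONS)
    )

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("vocabulary symbols must be distinct")
        for special in (self.bos, self.eos, self.pad):
            if special not in self.symbols:
                raise ValueError(f"special symbol {special!r} not in alphabet")
        for src, dst in self.substitutions.items():
            if dst not in self.symbols:
                raise ValueError(f"substitution target {dst!r} not in alphabet")
            if len(src) < 2:
                raise ValueError("substitution sources must be multi-character")

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def index_of(self) -> dict[str, int]:
        return {sym: i for i, sym in enumerate(self.symbols)}

    @property
    def bos_id(self) -> int:
        return self.symbols.index(self.bos)

    @property
    def eos_id(self) -> int:
        return self.symbols.index(self.eos)

    @property
    def pad_id(self) -> int:
        return self.symbols.index(self.pad)

    def to_json(self) -> str:
        return json.dumps(
            {
                "symbols": list(self.symbols),
                "bos": self.bos,
                "eos": self.eos,
                "pad": self.pad,
                "substitutions": self.substitutions,
            },
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "TokenVocabulary":
        obj = json.loads(text)
        return cls(
            symbols=tuple(obj["symbols"]),
            bos=obj["bos"],
            eos=obj["eos"],
            pad=obj["pad"],
            substitutions=dict(obj["substitutions"]),
        )


@dataclass(frozen=True)
class EncodedSmiles:
    """A padded, delimited encoding of one molecule.

    ``indices`` has fixed length ``L``; ``onehot`` is the ``L x s`` binary
    matrix with exactly one 1 per row; ``raw`` is the originating SMILES.
    """

    indices: np.ndarray
    onehot: np.ndarray
    raw: str

    @property
    def length(self) -> int:
        return int(self.indices.shape[0])


def build_default_vocabulary() -> TokenVocabulary:
    """Return the packaged 33-symbol alphabet."""
    return TokenVocabulary(symbols=tuple(_DEFAULT_SYMBOLS))


def _substitute(smiles: str, substitutions: dict[str, str]) -> str:
    for src, dst in substitutions.items():
        smiles = smiles.replace(src, dst)
    return smiles


def tokenize(smiles: str, vocab: TokenVocabulary | None = None) -> list[str]:
    """Split a curated SMILES into delimited single-character tokens.

    Halogen substitutions are applied first; then the string is split into
    characters, BoS is prepended and EoS appended.  No padding is applied.

    Raises
    ------
    VocabularyError
        If a character (after substitution) is not in the alphabet; the
        message names the character and its position.
    """
    if vocab is None:
        vocab = build_default_vocabulary()
    substituted = _substitute(smiles, vocab.substitutions)
    known = set(vocab.symbols)
    for pos, ch in enumerate(substituted):
        if ch not in known:
            raise VocabularyError(
                f"character {ch!r} at position {pos} of {smiles!r} "
                "is not in the vocabulary"
            )
    return [vocab.bos, *substituted, vocab.eos]


def pad_encode(
    tokens: Sequence[str],
    max_raw_len: int = DEFAULT_MAX_RAW_LEN,
    vocab: TokenVocabulary | None = None,
    raw: str | None = None,
) -> EncodedSmiles:
    """Pad a delimited token sequence to width ``L = max_raw_len + 2``.

    Returns integer indices and the ``L x s`` one-hot matrix.
    """
    if vocab is None:
        vocab = build_default_vocabulary()
    L = max_raw_len + 2
    if len(tokens) > L:
        raise ValueError(
            f"token sequence of length {len(tokens)} exceeds maximum length {L}"
        )
    idx = vocab.index_of
    indices = np.full(L, vocab.pad_id, dtype=np.int64)
    for i, tok in enumerate(tokens):
        indices[i] = idx[tok]
    onehot = np.zeros((L, vocab.size), dtype=np.float64)
    onehot[np.arange(L), indices] = 1.0
    if raw is None:
        raw = decode(indices, vocab)[0]
    return EncodedSmiles(indices=indices, onehot=onehot, raw=raw)


def decode(
    indices: Sequence[int] | np.ndarray, vocab: TokenVocabulary | None = None
) -> tuple[str, bool]:
    """Map token indices back to SMILES text.

    Strips BoS, stops at the first EoS, drops pads, and reverses the
    halogen substitutions.  Returns ``(smiles, truncated)`` where
    ``truncated`` is True when no EoS was present.
    """
    if vocab is None:
        vocab = build_default_vocabulary()
    chars: list[str] = []
    truncated = True
    for i, token_id in enumerate(indices):
        sym = vocab.symbols[int(token_id)]
        if sym == vocab.bos and i == 0:
            continue
        if sym == vocab.eos:
            truncated = False
            break
        if sym == vocab.pad:
            continue
        chars.append(sym)
    text = "".join(chars)
    for src, dst in vocab.substitutions.items():
        text = text.replace(dst, src)
    return text, truncated


def encode_smiles(
    smiles: str,
    max_raw_len: int = DEFAULT_MAX_RAW_LEN,
    vocab: TokenVocabulary | None = None,
) -> EncodedSmiles:
    """Tokenize and pad-encode in one step."""
    if vocab is None:
        vocab = build_default_vocabulary()
    return pad_encode(tokenize(smiles, vocab), max_raw_len, vocab, raw=smiles)
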