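"""Ancestral SMILES generation by inverse-CDF categorical sampling.

Generation starts from the begin-of-sequence symbol and repeatedly
feeds the growing prefix through the decoder.  The next symbol is drawn
from the softmax distribution ``p_k`` of the last position with the
inverse-CDF rule: draw ``r`` uniform on [0, 1) and pick the smallest
index ``i`` whose cumulative probability exceeds ``r``.  Generation
stops at the end-of-sequence symbol or when the encoding width is
exhausted (the string is then flagged truncated).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .codec import TokenVocabulary, build_default_vocabulary, decode
from .decoder import ParameterSet, _forward, _softmax

__all__ = [
    "DEFAULT_N_MOLECULES",
    "GenerationResult",
    "sample_index",
    "generate_one",
    "generate_set",
    "protein_stream_seed",
]

#: default number of molecules generated per protein
DEFAULT_N_MOLECULES = 1000


@dataclass(frozen=True)
class GenerationResult:
    """Molecules generated for one protein from one seeded stream."""

    protein_id: str
    smiles_list: tuple[str, ...]
    status: tuple[str, ...]  # "complete" | "truncated"
    seed: int
    n_requested: int

    def __post_init__(self) -> None:
        if len(self.smiles_list) != self.n_requested:
            raise ValueError("smiles_list length must equal n_requested")


def sample_index(p: np.ndarray, r: float) -> int:
    """Smallest index i with cumulative probability strictly above ``r``.

    ``p`` must be a probability vector (sums to 1 within 1e-6) and
    ``r`` must lie in [0, 1).  Deterministic given (p, r).
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a nonempty 1-D probability vector")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("p must be nonnegative and sum to 1 within 1e-6")
    if not (0.0 <= r < 1.0):
        raise ValueError("r must lie in [0, 1)")
    cum = np.cumsum(p)
    hits = np.nonzero(cum > r)[0]
    # cum[-1] may fall epsilon short of 1 for r close to 1
    return int(hits[0]) if hits.size else int(p.size - 1)


def generate_one(
    x: np.ndarray,
    params: ParameterSet,
    rng: np.random.Generator,
    vocab: Optional[TokenVocabulary] = None,
) -> tuple[str, str]:
    """Generate one SMILES string for the protein embedding ``x``.

    Returns ``(smiles, status)`` with status ``"complete"`` when the
    end-of-sequence symbol was produced, else ``"truncated"``.  The
    begin-of-sequence and padding symbols are structural delimiters and
    are masked out of the next-symbol distribution before sampling.
    """
    if vocab is None:
        vocab = build_default_vocabulary()
    cfg = params.config
    if vocab.size != cfg.vocab_size:
        raise ValueError(
            f"vocabulary size {vocab.size} != model vocabulary {cfg.vocab_size}"
        )
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (cfg.d_model,):
        raise ValueError(f"embedding has shape {x.shape}, expected ({cfg.d_model},)")

    prefix = [vocab.bos_id]
    status = "truncated"
    # at most seq_len - 1 generated symbols beyond BoS
    while len(prefix) < cfg.seq_len:
        logits, _ = _forward(
            params, np.asarray(prefix, dtype=np.int64)[None], x[None]
        )
        last = logits[0, -1].copy()
        # BoS and pad are structural delimiters, never sampled
        last[vocab.bos_id] = -np.inf
        last[vocab.pad_id] = -np.inf
        p = _softmax(last)
        r = float(rng.random())
        token = sample_index(p, r)
        prefix.append(token)
        if token == vocab.eos_id:
            status = "complete"
            break
    smiles, truncated = decode(prefix, vocab)
    if truncated:
        status = "truncated"
    return smiles, status


def protein_stream_seed(seed: int, protein_id: str) -> int:
    """Stable per-protein stream seed derived from (global seed, id)."""
    return (int(seed) * 2654435761 + zlib.adler32(protein_id.encode())) % (2**31)


def generate_set(
    x: np.ndarray,
    params: ParameterSet,
    n: int = DEFAULT_N_MOLECULES,
    seed: int = 0,
    protein_id: str = "",
    vocab: Optional[TokenVocabulary] = None,
) -> GenerationResult:
    """Draw ``n`` molecules for one protein from a single seeded stream."""
    if n < 1:
        raise ValueError("n must be >= 1")
    stream = protein_stream_seed(seed, protein_id)
    rng = np.random.default_rng(stream)
    smiles: list[str] = []
    status: list[str] = []
    for _ in range(n):
        s, st = generate_one(x, params, rng, vocab)
        smiles.append(s)
        status.append(st)
    return GenerationResult(
        protein_id=protein_id,
        smiles_list=tuple(smiles),
        status=tuple(status),
        seed=stream,
        n_requested=n,
    )
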