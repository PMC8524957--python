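"""Text-to-vector encoders behind a minimal contract.

The representation stage only needs a deterministic map from a string to a
fixed-length real vector (with the empty string mapping to the zero
vector).  The default encoder here is a signed character-n-gram feature
hashing encoder: fully deterministic, dependency-free, and adequate for
the template-generated corpora the package trains on.  Any object
satisfying :class:`TextEncoder` — e.g. a mean-pooled transformer sentence
embedder such as BioBERT — can be dropped in instead.
"""

from __future__ import annotations

import hashlib
from typing import Protocol, runtime_checkable

import numpy as np

__all__ = ["TextEncoder", "HashingTextEncoder"]


@runtime_checkable
class TextEncoder(Protocol):
    """Contract for text encoders used by the representation channels."""

    name: str
    dim: int

    def encode(self, text: str) -> np.ndarray:  # pragma: no cover - protocol
        """Return a deterministic real vector of length ``dim``; "" -> zeros."""
        ...


def _stable_hash(data: bytes) -> int:
    """64-bit hash that is stable across processes (unlike ``hash``)."""
    return int.from_bytes(hashlib.blake2b(data, digest_size=8).digest(), "little")


class HashingTextEncoder:
    """Signed character-n-gram feature hashing into a fixed-width vector.

    The text is lowercased and padded with word-boundary markers; every
    character n-gram for n in ``ngram_range`` is hashed to a bucket in
    ``[0, dim)`` with a +/-1 sign taken from a second hash bit, and bucket
    counts are accumulated.  The empty string encodes to the zero vector.

    Parameters
    ----------
    dim : int
        Output vector length (default 256).
    ngram_range : tuple[int, int]
        Inclusive range of character n-gram lengths (default (3, 5)).
    """

    def __init__(self, dim: int = 256, ngram_range: tuple[int, int] = (3, 5)) -> None:
        if dim <= 0:
            raise ValueError("dim must be positive")
        lo, hi = ngram_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid ngram_range")
        self.dim = dim
        self.ngram_range = ngram_range
        self.name = f"hash-{dim}-ngram{lo}{hi}"

    def encode(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=np.float64)
        if not text:
            return vec
        padded = " " + text.lower().strip() + " "
        lo, hi = self.ngram_range
        for n in range(lo, hi + 1):
            for i in range(len(padded) - n + 1):
                h = _stable_hash(padded[i : i + n].encode("utf-8"))
                bucket = h % self.dim
                sign = 1.0 if (h >> 32) & 1 else -1.0
                vec[bucket] += sign
        return vec

    def __repr__(self) -> str:
        return f"HashingTextEncoder(dim={self.dim}, ngram_range={self.ngram_range})"
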