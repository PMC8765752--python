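"""Compact integer encoding of nucleotide sequences.

All heavy routines in this package operate on ``uint8`` arrays with
A=0, C=1, G=2, T=3; any other character (gap, N, IUPAC ambiguity) maps
to 255 and is treated as non-comparable. The encoding is chosen so that
complementation is ``3 - code`` and an A<->G or C<->T exchange (a
transition) satisfies ``a ^ b == 2``.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
INVALID = np.uint8(255)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.full(256, ord("N"), dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _DECODE[_i] = ord(_b)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode a code array back to a string (invalid codes become 'N')."""
    return _DECODE[codes].tobytes().decode("ascii")


def complement(codes: np.ndarray) -> np.ndarray:
    out = 3 - codes.astype(np.int16)
    return np.where(codes < 4, out, codes).astype(np.uint8)


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (invalid codes pass through)."""
    return complement(codes)[::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random nucleotide codes of the given length."""
    return rng.integers(0, 4, size=length, dtype=np.int64).astype(np.uint8)
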