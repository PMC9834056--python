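"""Low-level nucleotide primitives shared by every module.

Sequences are plain Python strings over the uppercase alphabet ``ACGTN``.
For bulk numeric work (permutation nulls, window gathers) sequences are
encoded as ``int8`` arrays with A=0, C=1, G=2, T=3, N=4; a match between
two encoded bases requires equality *and* both codes < 4, so N never
matches anything, including another N.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGTN"
N_CODE = 4

_COMP = str.maketrans("ACGTN", "TGCAN")

# code -> complement code; N is self-complementary
COMP_CODES = np.array([3, 2, 1, 0, 4], dtype=np.int8)

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


class SequenceAlphabetError(ValueError):
    """A sequence contains characters outside A/C/G/T/N."""


def validate_seq(seq: str) -> str:
    """Uppercase ``seq`` and reject characters outside the alphabet."""
    seq = seq.upper()
    if seq.strip("ACGTN"):
        bad = sorted(set(seq) - set(ALPHABET))
        raise SequenceAlphabetError(f"invalid nucleotide characters: {bad!r}")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement over A/C/G/T/N (N maps to N)."""
    seq = validate_seq(seq)
    return seq.translate(_COMP)[::-1]


def complement(seq: str) -> str:
    """Base-wise complement without reversal."""
    seq = validate_seq(seq)
    return seq.translate(_COMP)


def encode(seq: str) -> np.ndarray:
    """Encode a validated sequence as an int8 code array."""
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        raise SequenceAlphabetError("sequence contains non-ACGTN characters")
    return arr


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[np.asarray(codes, dtype=np.int8)].tobytes().decode()


def bases_match(a: str, b: str) -> bool:
    """Single-base identity with N treated as never matching."""
    return a == b and a != "N" and b != "N"
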