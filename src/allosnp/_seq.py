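"""Byte-coded nucleotide sequences.

Sequences are held as ``numpy.uint8`` arrays with the coding
A=0, C=1, G=2, T=3, N=4.  Coordinates are 0-based half-open everywhere
inside the package; 1-based conversions happen only at the file-format
boundary (GFF3, VCF).
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

BASES = "ACGTN"

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement: A<->T, C<->G, N->N
_COMP = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into an uppercase string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis."""
    return _COMP[codes][..., ::-1]


def complement(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes]


def random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    """Uniform random A/C/G/T sequence."""
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def mutate_bases(rng: np.random.Generator, codes: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Return a copy with positions ``idx`` replaced by a random *different* base."""
    out = codes.copy()
    shift = rng.integers(1, 4, size=idx.size, dtype=np.uint8)
    out[idx] = (out[idx] + shift) % 4
    return out
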