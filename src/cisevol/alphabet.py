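"""DNA alphabet conventions shared across the package.

Bases are canonically indexed 0..3 in the order A, C, G, T. Ambiguity
codes and gaps are rejected wherever sequences enter the package.
"""

from __future__ import annotations

import numpy as np

NUCLEOTIDES = "ACGT"
NUC_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

#: complement permutation on base indices (A<->T, C<->G)
COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int64)

A, C, G, T = 0, 1, 2, 3

#: purine/pyrimidine class per base index (0 = purine {A,G}, 1 = pyrimidine {C,T})
BASE_CLASS = np.array([0, 1, 0, 1], dtype=np.int64)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as an int array; reject anything else."""
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq.upper()):
        try:
            out[i] = NUC_INDEX[ch]
        except KeyError:
            raise ValueError(
                f"invalid character {ch!r} at position {i}; only A/C/G/T allowed"
            ) from None
    return out


def decode_sequence(codes) -> str:
    return "".join(NUCLEOTIDES[int(c)] for c in codes)


def reverse_complement(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[np.asarray(codes)[::-1]]


def is_transition(u: int, v: int) -> bool:
    """True if u -> v is a transition (within purines or within pyrimidines)."""
    return u != v and BASE_CLASS[u] == BASE_CLASS[v]
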