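"""Low-level sequence encodings shared across the package.

Bases are encoded A=0, C=1, G=2, T=3.  The sentinel code 4 marks a strand
end ("no neighbour"), written ``-`` in all text interchange formats.
Coordinates are 0-based and half-open; a dimer is identified by the index
of its left base.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
END_CODE = 4
END_SYMBOL = "-"

_CODE = {b: i for i, b in enumerate(BASES)}

#: the 16 dimers in code order (index = 4*first + second)
DIMERS = tuple(a + b for a in BASES for b in BASES)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array.

    Raises ``ValueError`` on any character outside ACGT.
    """
    try:
        return np.array([_CODE[b] for b in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(
            f"sequence {seq!r} contains non-ACGT character {exc.args[0]!r}"
        ) from None


def decode_sequence(codes) -> str:
    codes = np.asarray(codes)
    if codes.size and codes.max() >= 4:
        raise ValueError("cannot decode end sentinel (code 4) into a base")
    return "".join(BASES[c] for c in codes)


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement of an ACGT string, 5'->3'."""
    encode_sequence(seq)  # validation only
    return str(Seq(seq.upper()).reverse_complement())


def enumerate_kmers(k: int) -> list[str]:
    """All 4**k k-mers in lexicographic (ACGT) order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return ["".join(BASES[d] for d in digits) for digits in np.ndindex(*(4,) * k)]


def kmer_code_matrix(k: int) -> np.ndarray:
    """(4**k, k) uint8 matrix of all k-mers in lexicographic order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = 4**k
    idx = np.arange(n)
    cols = [(idx // 4 ** (k - 1 - j)) % 4 for j in range(k)]
    return np.stack(cols, axis=1).astype(np.uint8)


def dimer_context_codes(codes: np.ndarray):
    """Per-dimer (left, dimer, right) code arrays for encoded strands.

    ``codes`` is (n_strands, L) or (L,).  Returns three arrays of shape
    (..., L-1): left neighbour code (4 at the 5' end), dimer index
    0..15, right neighbour code (4 at the 3' end).
    """
    codes = np.atleast_2d(np.asarray(codes))
    if codes.shape[1] < 2:
        raise ValueError("strands must have length >= 2 to contain a dimer")
    n, L = codes.shape
    left = np.full((n, L - 1), END_CODE, dtype=np.uint8)
    left[:, 1:] = codes[:, :-2]
    right = np.full((n, L - 1), END_CODE, dtype=np.uint8)
    right[:, :-1] = codes[:, 2:]
    dimer = (4 * codes[:, :-1].astype(np.intp)) + codes[:, 1:]
    return left, dimer, right
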