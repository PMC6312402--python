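"""Low-level DNA encodings shared across modules.

Barcodes and read fragments are compared by Hamming distance in bulk, so
sequences are packed into one-hot ``uint64`` words (4 bits per base, up to
16 nt per word). XOR + popcount of two such words equals twice the Hamming
distance, which turns a pairwise scan into a handful of vectorised numpy
ops. Ambiguous bases (N etc.) are encoded with no bit set; they contribute
one popcount bit against any concrete base and are corrected to a full
mismatch by the callers that allow them.
"""

from __future__ import annotations

import re
from collections.abc import Iterable

import numpy as np

BASES = "ACGT"
_BASE_TO_IDX = {b: i for i, b in enumerate(BASES)}

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC degenerate nucleotide codes.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


def is_iupac(seq: str) -> bool:
    return all(c in IUPAC for c in seq.upper())


def iupac_pattern(motif: str) -> re.Pattern[str]:
    """Compile a degenerate motif into a regex over plain ACGT strings."""
    parts = []
    for c in motif.upper():
        exp = IUPAC[c]
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return re.compile("".join(parts))


def seq_to_indices(seq: str, *, allow_ambiguous: bool = False) -> np.ndarray:
    """Map a DNA string to uint8 indices (A=0,C=1,G=2,T=3; ambiguous=255)."""
    out = np.empty(len(seq), dtype=np.uint8)
    for i, c in enumerate(seq.upper()):
        idx = _BASE_TO_IDX.get(c)
        if idx is None:
            if not allow_ambiguous or c not in IUPAC:
                raise ValueError(f"non-ACGT character {c!r} at position {i}")
            idx = 255
        out[i] = idx
    return out


def indices_to_seq(idx: np.ndarray) -> str:
    return "".join(BASES[i] for i in idx)


def onehot_codes(indices: np.ndarray) -> np.ndarray:
    """Pack index rows (n, L<=16) into one-hot uint64 codes (n,).

    Index 255 (ambiguous) sets no bit.
    """
    idx = np.atleast_2d(indices)
    n, L = idx.shape
    if L > 16:
        raise ValueError("one-hot packing supports at most 16 nt")
    codes = np.zeros(n, dtype=np.uint64)
    valid = idx != 255
    pos = np.arange(L, dtype=np.uint64)
    for j in range(L):
        mask = valid[:, j]
        bit = np.zeros(n, dtype=np.uint64)
        bit[mask] = np.uint64(1) << (np.uint64(4) * pos[j] + idx[mask, j].astype(np.uint64))
        codes |= bit
    return codes


def encode_seqs(seqs: Iterable[str], *, allow_ambiguous: bool = False) -> np.ndarray:
    """One-hot codes for equal-length DNA strings."""
    mat = np.stack([seq_to_indices(s, allow_ambiguous=allow_ambiguous) for s in seqs])
    return onehot_codes(mat)


def hamming_to_set(code: np.uint64, codes: np.ndarray) -> np.ndarray:
    """Hamming distances from one packed sequence to an array of them."""
    return np.bitwise_count(codes ^ code) >> 1
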