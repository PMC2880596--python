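"""Base-level sequence encoding shared by the counting machinery.

Sequences live in numpy ``uint8`` arrays with the code table below.  Codes
>= 4 (N, X) never compare equal to a base code, so any motif window that
touches an ambiguous or masked position drops out of every count without
special-casing.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N, X = 0, 1, 2, 3, 4, 5

ALPHABET = "ACGTNX"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(ALPHABET):
    _ENCODE[ord(_ch)] = _i
    _ENCODE[ord(_ch.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

# complement: A<->T, C<->G, N->N, X->X
_COMPLEMENT = np.array([T, G, C, A, N, X], dtype=np.uint8)

_COMP_STR = str.maketrans("ACGTNX", "TGCANX")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string into uint8 codes."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({ch for ch in seq.upper() if ch not in ALPHABET})
        raise ValueError(f"sequence contains non-{ALPHABET} characters: {bad}")
    return arr


def encode_matrix(seqs: list[str], length: int | None = None) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) uint8 matrix."""
    if not seqs:
        raise ValueError("empty sequence list")
    L = len(seqs[0]) if length is None else length
    for s in seqs:
        if len(s) != L:
            raise ValueError(f"sequence length {len(s)} != expected {L}")
    flat = _ENCODE[np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)]
    if (flat == 255).any():
        raise ValueError(f"sequences contain characters outside {ALPHABET}")
    return flat.reshape(len(seqs), L)


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def decode_matrix(mat: np.ndarray) -> list[str]:
    joined = _DECODE[mat.reshape(-1)].tobytes().decode("ascii")
    L = mat.shape[1]
    return [joined[i : i + L] for i in range(0, len(joined), L)]


def revcomp_codes(arr: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis; N and X map to themselves."""
    return _COMPLEMENT[arr][..., ::-1]


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence string (N->N, X->X)."""
    return seq.translate(_COMP_STR)[::-1]


def expand_iupac(pattern: str) -> list[str]:
    """Expand an IUPAC degenerate pattern into its literal ACGT words."""
    words = [""]
    for ch in pattern.upper():
        try:
            choices = IUPAC[ch]
        except KeyError:
            raise ValueError(f"not an IUPAC nucleotide code: {ch!r}") from None
        words = [w + c for w in words for c in choices]
    return words
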