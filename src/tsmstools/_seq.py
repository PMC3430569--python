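"""Small sequence helpers shared across modules (encoding, complement, GC)."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

# A=0, C=1, G=2, T=3; purines are the even codes.
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 codes (A=0, C=1, G=2, T=3)."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside {A,C,G,T}")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def is_purine_code(codes: np.ndarray) -> np.ndarray:
    """True where the code is A or G (template-strand purine)."""
    return codes % 2 == 0


def circular_slice(seq: str, start: int, end: int) -> str:
    """Slice with wrap-around; start in [0, len), end may exceed len."""
    n = len(seq)
    if end <= n:
        return seq[start:end]
    return seq[start:] + seq[: end - n]
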