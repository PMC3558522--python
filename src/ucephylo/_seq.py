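"""Small shared helpers for nucleotide sequences.

Internally sequences are encoded as uint8 arrays: A=0, C=1, G=2, T=3,
anything else (gap '-', '?', 'N') = 255 and is treated as missing.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
MISSING = 255

_ENC = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-", "?": "?"}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (255 = missing)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray, missing_char: str = "?") -> str:
    out = np.full(arr.shape, ord(missing_char), dtype=np.uint8)
    ok = arr < 4
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    out[ok] = lut[arr[ok]]
    return out.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq.upper()))


def kmers(seq: str, k: int):
    """Iterate over the k-mers of ``seq`` (uppercased)."""
    s = seq.upper()
    for i in range(len(s) - k + 1):
        yield s[i : i + k]
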