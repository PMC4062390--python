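"""Nucleotide alphabet helpers shared across the package.

Sequences are plain upper-case strings over {A,C,G,T,N}; for numeric work
they are encoded as int8 arrays with A=0, C=1, G=2, T=3, N=4.  N marks an
unknown base: windows containing it are treated as unscorable everywhere.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
N_CODE = 4

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC degenerate nucleotide codes -> the set of bases each stands for
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_ENCODE_TABLE = np.full(256, N_CODE, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a normalized sequence as int8 codes (N and anything else -> 4)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def iupac_matches(code: str, base: str) -> bool:
    """True if `base` is in the degenerate set of IUPAC `code`."""
    return base in IUPAC[code]


def validate_iupac(pattern: str) -> None:
    if not pattern:
        raise ValueError("empty IUPAC pattern")
    bad = [c for c in pattern if c not in IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {bad!r} in pattern {pattern!r}")
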