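"""Low-level DNA sequence helpers shared across the package.

Coordinates everywhere in the package are 0-based, half-open.
"""
from __future__ import annotations

import numpy as np

#: IUPAC nucleotide codes -> set of concrete bases they admit.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RC = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn", "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (full IUPAC alphabet)."""
    return seq.translate(_RC)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming distance needs equal lengths, got {len(a)} and {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def matches_iupac(seq: str, pattern: str) -> bool:
    """True if ``seq`` matches the IUPAC ``pattern`` position by position."""
    if len(seq) != len(pattern):
        return False
    try:
        return all(base in IUPAC[sym] for base, sym in zip(seq.upper(), pattern.upper()))
    except KeyError as exc:  # unknown pattern symbol
        raise ValueError(f"unknown IUPAC symbol in pattern {pattern!r}") from exc


def seq_to_uint8(seq: str) -> np.ndarray:
    """ASCII byte view of a sequence, for vectorised scans."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
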