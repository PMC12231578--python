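"""Small DNA sequence utilities shared across the package."""

from __future__ import annotations

import re

import numpy as np

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: IUPAC degenerate base -> set of concrete bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_DNA_RE = re.compile(r"^[ACGT]*$")

BASES = np.array(["A", "C", "G", "T"])


def is_dna(seq: str) -> bool:
    """True if ``seq`` consists only of the concrete bases A/C/G/T."""
    return bool(_DNA_RE.match(seq))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC DNA pattern into a regular expression."""
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"not an IUPAC DNA code: {ch!r}")
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def iupac_match(base: str, code: str) -> bool:
    """True if concrete ``base`` is allowed by IUPAC ``code``."""
    return base in IUPAC[code.upper()]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random DNA with i.i.d. bases, P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if length == 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[idx])
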