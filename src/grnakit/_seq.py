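"""Low-level DNA helpers shared across modules: alphabets, reverse
complement, IUPAC matching and 2-bit/numpy encodings."""

from __future__ import annotations

import numpy as np

# IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_DNA = frozenset(IUPAC_SETS)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)

# Base -> small-int encoding used by the numpy kernels. 4 == "not ACGT".
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_iupac_dna(seq: str) -> bool:
    return all(c in IUPAC_DNA for c in seq)


def pam_matches(pattern: str, observed: str) -> bool:
    """IUPAC semantics on the pattern side only: an ambiguity code in the
    observed (genomic) sequence never matches, so N-runs in assemblies do
    not spawn phantom PAM sites."""
    if len(pattern) != len(observed):
        return False
    return all(o in IUPAC_SETS[p] for p, o in zip(pattern, observed))


def encode(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, anything else 4; uint8 array."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[arr].tobytes().decode("ascii")


def pam_code_sets(pattern: str) -> list[np.ndarray]:
    """Per-position arrays of allowed base codes (never code 4)."""
    return [
        np.array(sorted("ACGT".index(b) for b in IUPAC_SETS[p]), dtype=np.uint8)
        for p in pattern
    ]
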