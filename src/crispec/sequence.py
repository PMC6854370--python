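"""Small DNA sequence utilities shared across modules."""

from __future__ import annotations

DNA = "ACGT"

_COMP = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn", "TGCAYRMKVHDBNtgcayrmkvhdbn")

#: IUPAC ambiguity codes -> set of genome bases each code accepts.
#: ``N`` additionally accepts an ``N`` in the genome (anything-matches-anything);
#: every other code requires an unambiguous base.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes and case."""
    return seq.translate(_COMP)[::-1]


def matches_iupac(pattern: str, seq: str) -> bool:
    """True if ``seq`` matches the IUPAC ``pattern`` base-for-base."""
    if len(pattern) != len(seq):
        return False
    try:
        return all(base in IUPAC[p] for p, base in zip(pattern.upper(), seq.upper()))
    except KeyError as exc:  # pattern contains a non-IUPAC character
        raise ValueError(f"invalid IUPAC code in pattern {pattern!r}: {exc}") from exc


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def is_primitive(unit: str) -> bool:
    """True if ``unit`` is not itself a repetition of a shorter unit."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def is_acgt(seq: str) -> bool:
    return bool(seq) and set(seq) <= set(DNA)
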