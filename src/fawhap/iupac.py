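"""IUPAC nucleotide-ambiguity helpers.

Sanger consensus sequences from diploid (male, ZZ) specimens encode
heterozygous positions as ambiguity codes, so most of the pipeline reasons
about *sets* of bases rather than single letters.
"""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
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
    "N": frozenset("ACGT"),
}

SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

UNAMBIGUOUS = frozenset("ACGT")


def bases(code: str) -> frozenset[str]:
    """Set of unambiguous bases admitted by an IUPAC code."""
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def code_for(base_set: frozenset[str] | set[str]) -> str:
    """IUPAC code for a nonempty set of unambiguous bases."""
    return SET_TO_CODE[frozenset(base_set)]


def union_code(a: str, b: str) -> str:
    """IUPAC code displaying both alleles of a heterozygote at one site."""
    return code_for(bases(a) | bases(b))


def is_unambiguous(code: str) -> bool:
    return code.upper() in UNAMBIGUOUS


def compatible(a: str, b: str) -> bool:
    """True if the two codes admit at least one common base."""
    return bool(bases(a) & bases(b))


def valid_sequence(seq: str) -> bool:
    """True if every character is an IUPAC nucleotide code."""
    return all(c.upper() in IUPAC_SETS for c in seq)
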