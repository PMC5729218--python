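"""IUPAC nucleotide ambiguity codes: expansion sets, complements, degeneracy.

All sequence-level logic in the package goes through these tables so that
degenerate primers are handled identically in consensus building, melting
temperature, and binding-site scoring.
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

#: inverse of IUPAC_SETS: frozenset of bases -> single-letter code
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)
DNA_ALPHABET = frozenset("ACGTN")


class InvalidBaseError(ValueError):
    """A character outside the IUPAC nucleotide alphabet."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid IUPAC base {char!r} at position {position}"
        )


def validate(sequence: str) -> str:
    """Uppercase *sequence* and raise :class:`InvalidBaseError` on any
    character outside the 15-letter IUPAC alphabet."""
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in IUPAC_SETS:
            raise InvalidBaseError(ch, i)
    return seq


def expansion(code: str) -> frozenset[str]:
    """The set of concrete bases a single IUPAC code stands for."""
    try:
        return IUPAC_SETS[code]
    except KeyError:
        raise InvalidBaseError(code, 0) from None


def code_for(bases: frozenset[str] | set[str]) -> str:
    """The unique IUPAC code for a nonempty subset of {A,C,G,T}."""
    return CODE_FOR_SET[frozenset(bases)]


def degeneracy(sequence: str) -> int:
    """Product of per-position expansion-set sizes (number of concrete
    sequences a degenerate oligo encodes)."""
    d = 1
    for ch in validate(sequence):
        d *= len(IUPAC_SETS[ch])
    return d


def revcomp(sequence: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H;
    S, W, N are self-complementary)."""
    seq = validate(sequence)
    return "".join(COMPLEMENT[ch] for ch in reversed(seq))


def matches(primer_base: str, target_base: str) -> bool:
    """True when *target_base* is compatible with *primer_base*.

    A target position matches when it is a member of the primer base's
    expansion set; an ``N`` in the target (reference ambiguity) matches any
    primer base, so database uncertainty never penalizes a primer.
    """
    if target_base == "N":
        return True
    return target_base in IUPAC_SETS[primer_base]
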