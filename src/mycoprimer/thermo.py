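"""Oligonucleotide GC content, melting temperature, and pair ΔTm.

Three composition-only Tm formulas are pinned (the classic oligo-calculator
equations), so a primer's Tm is a deterministic function of its sequence:

* ``wallace``       Tm = 2(A+T) + 4(G+C)                       (short oligos)
* ``basic``         Tm = 64.9 + 41*(GC - 16.4)/N               (N >= 14)
* ``salt_adjusted`` Tm = 100.5 + 41*GC/N - 820/N + 16.6*log10([Na+])

Degenerate IUPAC positions contribute fractionally: an R counts half a
purine-A and half a G, so one number describes the whole primer mixture.
Pairing of a forward and a reverse primer is screened on |ΔTm|; the
conventional cutoff is 5 °C but the threshold is always the caller's
parameter, never baked in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from . import iupac

TM_METHODS = ("wallace", "basic", "salt_adjusted")


@dataclass(frozen=True)
class Oligo:
    """A named 5'->3' IUPAC primer."""

    name: str
    sequence: str
    direction: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"{self.name}: direction must be forward or reverse")
        object.__setattr__(self, "sequence", iupac.validate(self.sequence))
        if not self.sequence:
            raise ValueError(f"{self.name}: empty sequence")

    @property
    def degeneracy(self) -> int:
        return iupac.degeneracy(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def gc_fraction(sequence: str) -> float:
    """Mean per-position G+C content in [0, 1].

    Each position contributes the fraction of its IUPAC expansion set that
    is G or C: A -> 0, S -> 1, R -> 0.5, N -> 0.5.
    """
    seq = iupac.validate(sequence)
    if not seq:
        raise ValueError("empty sequence")
    total = 0.0
    for ch in seq:
        bases = iupac.IUPAC_SETS[ch]
        total += sum(1 for b in bases if b in "GC") / len(bases)
    return total / len(seq)


def melting_temp(
    sequence: str, method: str = "basic", na_molar: float = 0.05
) -> float:
    """Melting temperature in °C under one of the pinned formulas.

    ``na_molar`` (monovalent cation concentration, mol/L) only enters the
    salt-adjusted formula; default 0.05 M.  The Wallace rule is meant for
    oligos under 14 bases and warns (but still computes) beyond that.
    """
    seq = iupac.validate(sequence)
    if not seq:
        raise ValueError("empty sequence")
    if method not in TM_METHODS:
        raise ValueError(f"unknown Tm method {method!r}; choose from {TM_METHODS}")
    if na_molar <= 0:
        raise ValueError("na_molar must be positive")
    n = len(seq)
    gc_count = gc_fraction(seq) * n  # fractional for degenerate oligos
    if method == "wallace":
        if n >= 14:
            warnings.warn(
                f"Wallace rule applied to a {n}-mer; intended for oligos "
                "shorter than 14 bases",
                stacklevel=2,
            )
        return 2.0 * (n - gc_count) + 4.0 * gc_count
    if method == "basic":
        return 64.9 + 41.0 * (gc_count - 16.4) / n
    # salt_adjusted
    return 100.5 + 41.0 * gc_count / n - 820.0 / n + 16.6 * math.log10(na_molar)


def pair_tm_diff(fwd: Oligo, rev: Oligo, method: str = "basic",
                 na_molar: float = 0.05) -> float:
    """|Tm(forward) - Tm(reverse)| under one method, in °C.

    Symmetric and non-negative; comparing against a cutoff (e.g. the
    conventional 5 °C) is the caller's job.
    """
    return abs(
        melting_temp(fwd.sequence, method, na_molar)
        - melting_temp(rev.sequence, method, na_molar)
    )
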