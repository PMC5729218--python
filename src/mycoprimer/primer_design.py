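"""Degenerate candidate primers from a multiple alignment, and pair screening.

Candidate generation slides a fixed-length window over a gapped alignment
(forward candidates come from the 3' 18S design window, reverse candidates
from the conserved 5.8S region).  Each window's IUPAC consensus includes
every base observed at >= ``min_freq`` in a column; candidates are kept when
their degeneracy (number of encoded concrete sequences) stays within bounds
and the consensus exactly matches enough alignment rows (sensitivity).

Pair screening enumerates forward x reverse combinations against a SIS
contig database and retains pairs with a small melting-temperature
difference and a mean predicted amplicon length inside the sequencer-facing
window (400 ± 100 bp by default, hard cap 700 bp).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from . import insilico_pcr, iupac, thermo
from .sisdb import SisContig
from .thermo import Oligo

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class AlignmentWindow:
    """Per-column base frequencies for one window of a gapped alignment.

    ``column_freqs[i]`` maps each concrete base to its fraction among the
    non-gap characters of column ``start_col + i``; the gap fraction is
    tracked separately and non-gap fractions sum to 1.
    """

    start_col: int
    length: int
    column_freqs: tuple[dict[str, float], ...]
    gap_fracs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.length < 1 or len(self.column_freqs) != self.length:
            raise ValueError("window length must be >= 1 and match freqs")


@dataclass(frozen=True)
class PrimerCandidate:
    consensus: str
    start_col: int
    degeneracy: int
    sensitivity: float


@dataclass(frozen=True)
class PairRecord:
    """One screened forward/reverse combination with its screening stats."""

    fwd: Oligo
    rev: Oligo
    tm_diff: float
    mean_amplicon: float
    sd_amplicon: float | None
    coverage: float
    n_amplicons: int


class AlignmentError(ValueError):
    pass


def read_alignment(path: str | Path) -> list[str]:
    """Load gapped FASTA rows (uppercased, U->T); checks equal lengths."""
    rows = [str(r.seq).upper().replace("U", "T") for r in SeqIO.parse(str(path), "fasta")]
    _check_alignment(rows)
    return rows


def _check_alignment(rows: Sequence[str]) -> None:
    if len(rows) < 2:
        raise AlignmentError("alignment needs >= 2 rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise AlignmentError("ragged alignment: rows differ in length")


def window_freqs(rows: Sequence[str], start_col: int, length: int) -> AlignmentWindow:
    """Column base frequencies for ``rows[:, start_col:start_col+length]``."""
    freqs = []
    gaps = []
    n_rows = len(rows)
    for j in range(start_col, start_col + length):
        counts: dict[str, int] = {}
        n_gap = 0
        for r in rows:
            ch = r[j]
            if ch in GAP_CHARS:
                n_gap += 1
            else:
                counts[ch] = counts.get(ch, 0) + 1
        n_base = n_rows - n_gap
        freqs.append(
            {b: c / n_base for b, c in counts.items()} if n_base else {}
        )
        gaps.append(n_gap / n_rows)
    return AlignmentWindow(start_col, length, tuple(freqs), tuple(gaps))


def iupac_consensus_window(window: AlignmentWindow, min_freq: float = 0.10) -> str:
    """Degenerate consensus of one window.

    Per column: include every concrete base with frequency >= *min_freq*
    and encode the set as its IUPAC code; when no base reaches the
    threshold, fall back to the single most frequent base (ties broken
    alphabetically).  Ambiguity codes in rows are expanded fractionally
    before thresholding.
    """
    if window.length == 0:
        raise ValueError("empty window")
    out = []
    for freq in window.column_freqs:
        if not freq:
            raise ValueError("column with no non-gap bases has no consensus")
        # expand row ambiguity codes onto concrete bases
        concrete: dict[str, float] = {}
        for ch, f in freq.items():
            bases = iupac.expansion(ch)
            for b in bases:
                concrete[b] = concrete.get(b, 0.0) + f / len(bases)
        included = {b for b, f in concrete.items() if f >= min_freq}
        if not included:
            top = max(sorted(concrete), key=lambda b: concrete[b])
            included = {top}
        out.append(iupac.code_for(included))
    return "".join(out)


def _row_matches(row: str, start_col: int, consensus: str) -> bool:
    """A row matches when it is gap-free in the window and every base lies
    in the consensus expansion set at its column."""
    for i, code in enumerate(consensus):
        ch = row[start_col + i]
        if ch in GAP_CHARS:
            return False
        if not iupac.expansion(ch) <= iupac.expansion(code):
            return False
    return True


def generate_candidates(
    rows: Sequence[str],
    primer_len: int = 20,
    min_freq: float = 0.10,
    max_degeneracy: int = 8,
    min_sensitivity: float = 0.60,
    max_gap_frac: float = 0.5,
) -> list[PrimerCandidate]:
    """Ranked degenerate primer candidates from a gapped alignment.

    Windows containing any column with gap fraction >= *max_gap_frac* are
    skipped.  Candidates failing the degeneracy or sensitivity bounds are
    dropped; the rest are ranked by (sensitivity desc, degeneracy asc,
    start column asc) — a total order independent of row order.
    """
    _check_alignment(rows)
    width = len(rows[0])
    if primer_len > width:
        raise AlignmentError(
            f"primer length {primer_len} exceeds alignment width {width}"
        )
    candidates = []
    for start in range(width - primer_len + 1):
        win = window_freqs(rows, start, primer_len)
        if any(g >= max_gap_frac for g in win.gap_fracs):
            continue
        consensus = iupac_consensus_window(win, min_freq)
        deg = iupac.degeneracy(consensus)
        if deg > max_degeneracy:
            continue
        n_match = sum(_row_matches(r, start, consensus) for r in rows)
        sens = n_match / len(rows)
        if sens < min_sensitivity:
            continue
        candidates.append(PrimerCandidate(consensus, start, deg, sens))
    candidates.sort(key=lambda c: (-c.sensitivity, c.degeneracy, c.start_col))
    return candidates


def enumerate_pairs(
    forwards: Sequence[Oligo],
    reverses: Sequence[Oligo],
    contigs: Sequence[SisContig],
    tm_method: str = "basic",
    max_tm_diff: float = 5.0,
    amp_mean_low: float = 300.0,
    amp_mean_high: float = 500.0,
    amp_hard_max: int = 700,
    score_threshold: float = insilico_pcr.DEFAULT_SCORE_THRESHOLD,
) -> list[PairRecord]:
    """Screen every forward x reverse pair against the contig database.

    A pair is retained when |ΔTm| < *max_tm_diff* and its mean predicted
    amplicon length (over amplicons <= *amp_hard_max*) lies in
    [*amp_mean_low*, *amp_mean_high*].  Output is sorted by coverage
    descending (ties by primer names), so it does not depend on the order
    of the input primer lists.
    """
    records = []
    for f in forwards:
        for r in reverses:
            dt = thermo.pair_tm_diff(f, r, tm_method)
            if dt >= max_tm_diff:
                continue
            mean, sd, n = insilico_pcr.amplicon_stats(
                f, r, contigs, score_threshold, amp_hard_max
            )
            if n == 0 or not (amp_mean_low <= mean <= amp_mean_high):
                continue
            report = insilico_pcr.evaluate_coverage(
                f, r, contigs, score_threshold, amp_hard_max=amp_hard_max
            )
            records.append(
                PairRecord(
                    fwd=f,
                    rev=r,
                    tm_diff=dt,
                    mean_amplicon=mean,
                    sd_amplicon=sd,
                    coverage=report.overall.coverage,
                    n_amplicons=n,
                )
            )
    records.sort(key=lambda p: (-p.coverage, p.fwd.name, p.rev.name))
    return records


# ---------------------------------------------------------------------------
# Primer list I/O (TSV: name, direction, sequence)

def read_primer_tsv(path: str | Path) -> list[Oligo]:
    """Read a primer list: TSV columns name, direction, sequence (header
    optional); enforces unique names."""
    oligos = []
    seen = set()
    with Path(path).open() as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: expected 3 tab-separated fields")
            name, direction, seq = parts[0], parts[1].lower(), parts[2]
            if line_no == 1 and direction not in ("forward", "reverse"):
                continue  # header row
            if name in seen:
                raise ValueError(f"{path}:{line_no}: duplicate primer name {name!r}")
            seen.add(name)
            oligos.append(Oligo(name, seq, direction))
    return oligos


def write_primer_tsv(oligos: Sequence[Oligo], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("name\tdirection\tsequence\n")
        for o in oligos:
            fh.write(f"{o.name}\t{o.direction}\t{o.sequence}\n")
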