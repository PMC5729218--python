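"""In-silico PCR: weighted mismatch scoring, amplicon prediction, coverage.

A primer is slid over every offset of every SIS contig (gapless model, no
indels) and each placement is scored with 3'-weighted mismatch penalties:
mismatches in the body of the primer cost 0.4, mismatches in the four bases
preceding the 3' terminus cost 1.0, and a mismatched 3'-terminal base —
which blocks polymerase extension — costs 3.0.  A contig counts as
amplified when the best forward and reverse placements both score at or
below a threshold (default 1.0) in productive orientation and the implied
amplicon is no longer than a hard cap (default 700 bp, the short-read
platform limit).  Coverage is reported per taxonomic group and overall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import iupac
from .iupac import revcomp  # re-exported: the site search needs it and so do callers
from .sisdb import SisContig
from .taxonomy import UNITE_RANKS, is_placeholder
from .thermo import Oligo

#: pinned scoring weights (the in-silico PCR scorer's published defaults)
WEIGHT_NON3 = 0.4
WEIGHT_3 = 1.0
WEIGHT_LAST = 3.0
THREE_PRIME_LEN = 5  # final 5 bases; the terminal one is scored separately
DEFAULT_SCORE_THRESHOLD = 1.0
DEFAULT_AMP_HARD_MAX = 700

# integer weights in tenths, so scores are exact and ties break by position
_W10_NON3 = round(WEIGHT_NON3 * 10)
_W10_3 = round(WEIGHT_3 * 10)
_W10_LAST = round(WEIGHT_LAST * 10)


@dataclass(frozen=True)
class BindingSite:
    """A scored primer placement on a contig (0-based, half-open)."""

    contig_id: str
    start: int
    end: int
    strand: str  # "plus" | "minus"
    n_mismatch_non3: int
    n_mismatch_3: int
    last_base_mismatch: bool
    score: float


@dataclass(frozen=True)
class AmpliconPrediction:
    """A productive forward/reverse placement pair and the PCR product span.

    The amplicon runs from the forward primer's 5' start to the reverse
    site's end on the plus strand — both primer footprints included, as a
    sequencer would see the product.
    """

    contig_id: str
    start: int
    end: int
    fwd_site: BindingSite
    rev_site: BindingSite

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GroupCoverage:
    n_records: int
    n_hits: int

    @property
    def coverage(self) -> float:
        return self.n_hits / self.n_records if self.n_records else 0.0


@dataclass(frozen=True)
class CoverageReport:
    """Per-group and overall fractions of contigs predicted to amplify."""

    per_group: dict[str, GroupCoverage]
    overall: GroupCoverage
    score_threshold: float
    grouping_rank: str
    #: secondary, species-level view (distinct species with >= 1 hit contig)
    species_overall: GroupCoverage


def score_site(primer: str, target_window: str) -> tuple[int, int, bool, float]:
    """Score one gapless placement of *primer* against an equal-length window.

    A position matches when the target base lies in the primer base's IUPAC
    expansion set (target N matches anything).  Mismatches are partitioned:
    terminal base / the 4 bases preceding it / the remainder, weighted
    3.0 / 1.0 / 0.4.  Returns (n_non3, n_3, last_mismatch, score).
    """
    if len(primer) != len(target_window):
        raise ValueError(
            f"primer length {len(primer)} != window length {len(target_window)}"
        )
    n = len(primer)
    n_non3 = n_3 = 0
    last_mm = False
    three_prime_start = max(n - THREE_PRIME_LEN, 0)
    for i in range(n):
        if iupac.matches(primer[i], target_window[i]):
            continue
        if i == n - 1:
            last_mm = True
        elif i >= three_prime_start:
            n_3 += 1
        else:
            n_non3 += 1
    # exact tenths: equal-score ties must be exact, not float-noise ordered
    score = (_W10_NON3 * n_non3 + _W10_3 * n_3 + _W10_LAST * last_mm) / 10.0
    return n_non3, n_3, last_mm, score


# -- fast vectorized scan ----------------------------------------------------

_CODE_BITS = {b: 1 << i for i, b in enumerate("ACGT")}


def _seq_bits(seq: str) -> np.ndarray:
    """Per-position bitmask of the expansion set (target N = all bases)."""
    return np.array(
        [sum(_CODE_BITS[b] for b in iupac.expansion(ch)) for ch in seq],
        dtype=np.uint8,
    )


def _scan_scores(primer: str, text: str, three_prime_left: bool = False) -> np.ndarray:
    """Scores of *primer* at every offset of *text* (vectorized over offsets).

    *primer* is given in plus-strand orientation.  For a reverse-strand
    search the caller passes the reverse complement and sets
    ``three_prime_left``: the biological 3' terminus then sits at the
    window's left edge, so the position weights are mirrored.
    """
    n, m = len(primer), len(text)
    n_off = m - n + 1
    if n_off <= 0:
        return np.empty(0)
    pbits = _seq_bits(primer)
    tbits = _seq_bits(text)
    # windows[o, i] = text base o+i compatible with primer base i
    idx = np.arange(n_off)[:, None] + np.arange(n)[None, :]
    match = (tbits[idx] & pbits[None, :]) != 0
    mm = ~match
    weights = np.full(n, _W10_NON3, dtype=np.int64)
    weights[max(n - THREE_PRIME_LEN, 0):] = _W10_3
    weights[n - 1] = _W10_LAST
    if three_prime_left:
        weights = weights[::-1]
    return (mm @ weights) / 10.0


def find_best_site(
    primer: Oligo | str,
    contig: SisContig,
    strand: str,
    min_start: int = 0,
) -> BindingSite | None:
    """Exhaustive best-scoring placement of *primer* on *contig*.

    For ``strand="minus"`` the primer binds the reverse strand: its reverse
    complement is compared against the plus-strand text, so the primer's 3'
    terminus maps to the window's left edge.  Ties go to the smallest start.
    Returns None when the contig is shorter than the primer (or no offset
    >= *min_start* exists).
    """
    if strand not in ("plus", "minus"):
        raise ValueError(f"strand must be plus or minus, got {strand!r}")
    pseq = primer.sequence if isinstance(primer, Oligo) else iupac.validate(primer)
    text = contig.sequence
    n = len(pseq)
    if len(text) < n:
        return None
    query = pseq if strand == "plus" else revcomp(pseq)
    scores = _scan_scores(query, text, three_prime_left=(strand == "minus"))
    if min_start > 0:
        scores = scores[min_start:]
    if scores.size == 0:
        return None
    o = int(np.argmin(scores))  # argmin takes the first == smallest start
    start = o + min_start
    window = text[start: start + n]
    oriented = window if strand == "plus" else revcomp(window)
    n_non3, n_3, last_mm, score = score_site(pseq, oriented)
    return BindingSite(
        contig_id=contig.contig_id,
        start=start,
        end=start + n,
        strand=strand,
        n_mismatch_non3=n_non3,
        n_mismatch_3=n_3,
        last_base_mismatch=last_mm,
        score=float(score),
    )


def predict_amplicon(
    fwd: Oligo, rev: Oligo, contig: SisContig
) -> AmpliconPrediction | None:
    """Best forward site (plus strand) paired with the best reverse site
    (minus strand) downstream of it; None when either is absent or no
    reverse placement starts at or after the forward site's end."""
    f = find_best_site(fwd, contig, "plus")
    if f is None:
        return None
    r = find_best_site(rev, contig, "minus", min_start=f.end)
    if r is None:
        return None
    return AmpliconPrediction(
        contig_id=contig.contig_id,
        start=f.start,
        end=r.end,
        fwd_site=f,
        rev_site=r,
    )


def _is_hit(
    amp: AmpliconPrediction | None,
    score_threshold: float,
    amp_hard_max: int,
) -> bool:
    return (
        amp is not None
        and amp.fwd_site.score <= score_threshold
        and amp.rev_site.score <= score_threshold
        and amp.length <= amp_hard_max
    )


def evaluate_coverage(
    fwd: Oligo,
    rev: Oligo,
    contigs: Sequence[SisContig],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    grouping_rank: str = "phylum",
    extra_groups: Sequence[tuple[str, str]] = (("genus", "candida"),),
    amp_hard_max: int = DEFAULT_AMP_HARD_MAX,
) -> CoverageReport:
    """Predicted taxonomic coverage of one primer pair over the database.

    A contig is a hit when both best binding sites score at or below
    *score_threshold* and the predicted amplicon is at most *amp_hard_max*
    bases.  Hits are grouped by the contig lineage's *grouping_rank*, with
    extra named rows (by default the genus *Candida*, the medically central
    genus) reported alongside; extra rows overlap the rank groups and are
    excluded from the overall sums.
    """
    if not contigs:
        raise ValueError("contigs collection is empty")
    if grouping_rank not in UNITE_RANKS:
        raise ValueError(f"unknown grouping rank {grouping_rank!r}")
    for rank, _name in extra_groups:
        if rank not in UNITE_RANKS:
            raise ValueError(f"unknown rank {rank!r} in extra_groups")

    group_records: dict[str, int] = {}
    group_hits: dict[str, int] = {}
    extra_records: dict[str, int] = {g: 0 for _, g in extra_groups}
    extra_hits: dict[str, int] = {g: 0 for _, g in extra_groups}
    n_hits = 0
    species_seen: set[str] = set()
    species_hit: set[str] = set()
    for c in contigs:
        amp = predict_amplicon(fwd, rev, c)
        hit = _is_hit(amp, score_threshold, amp_hard_max)
        group = c.lineage.name(grouping_rank)
        group_records[group] = group_records.get(group, 0) + 1
        group_hits[group] = group_hits.get(group, 0) + int(hit)
        n_hits += int(hit)
        sp = c.lineage.name("species")
        if not is_placeholder(sp):
            species_seen.add(sp)
            if hit:
                species_hit.add(sp)
        for rank, name in extra_groups:
            if c.lineage.name(rank) == name:
                extra_records[name] += 1
                extra_hits[name] += int(hit)

    per_group = {
        g: GroupCoverage(group_records[g], group_hits[g])
        for g in sorted(group_records)
    }
    for _, name in extra_groups:
        if extra_records[name]:
            per_group[name] = GroupCoverage(extra_records[name], extra_hits[name])
    return CoverageReport(
        per_group=per_group,
        overall=GroupCoverage(len(contigs), n_hits),
        score_threshold=score_threshold,
        grouping_rank=grouping_rank,
        species_overall=GroupCoverage(len(species_seen), len(species_hit)),
    )


def amplicon_stats(
    fwd: Oligo,
    rev: Oligo,
    contigs: Sequence[SisContig],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    amp_hard_max: int = DEFAULT_AMP_HARD_MAX,
) -> tuple[float | None, float | None, int]:
    """Sample mean and sample SD (n-1 denominator) of predicted amplicon
    lengths over hit contigs; (None, None, 0) with no hits, SD None at n=1."""
    lengths = []
    for c in contigs:
        amp = predict_amplicon(fwd, rev, c)
        if _is_hit(amp, score_threshold, amp_hard_max):
            lengths.append(amp.length)
    n = len(lengths)
    if n == 0:
        return None, None, 0
    mean = float(np.mean(lengths))
    sd = float(np.std(lengths, ddof=1)) if n > 1 else None
    return mean, sd, n


def predict_all(
    fwd: Oligo, rev: Oligo, contigs: Iterable[SisContig]
) -> list[AmpliconPrediction]:
    """Amplicon predictions (unfiltered) for every contig that yields one."""
    out = []
    for c in contigs:
        amp = predict_amplicon(fwd, rev, c)
        if amp is not None:
            out.append(amp)
    return out
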