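"""Construction of the merged 18S-ITS1-5.8S ("SIS") reference database.

No public database carries the intact 18S-ITS1-5.8S region, so it is
simulated: each ITS record is matched by taxonomy to an 18S reference and
the two sequences are concatenated into one contig.  The full 18S is kept
(not only the 3' design window) so that candidate forward primers can be
screened against every conserved 18S site they might also bind.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .taxonomy import (
    Lineage,
    MatchResult,
    SilvaNameIndex,
    TaxRecord,
    is_placeholder,
    match_lowest_level,
    parse_lineage,
)


@dataclass(frozen=True)
class SisContig:
    """One simulated 18S-ITS1-5.8S contig with provenance.

    ``sequence[:join_pos]`` is the 18S reference verbatim and
    ``sequence[join_pos:]`` the ITS record verbatim; ``join_pos`` is the
    0-based index of the first ITS-derived base.
    """

    contig_id: str
    sequence: str
    join_pos: int
    unite_id: str
    silva_id: str
    match_rank: str
    lineage: Lineage  # the seven-rank ITS-side lineage (authoritative)

    def __post_init__(self) -> None:
        if not (1 <= self.join_pos < len(self.sequence)):
            raise ValueError(
                f"{self.contig_id}: join_pos {self.join_pos} outside contig"
            )

    @property
    def silva_part(self) -> str:
        return self.sequence[: self.join_pos]

    @property
    def unite_part(self) -> str:
        return self.sequence[self.join_pos:]


@dataclass(frozen=True)
class SisStats:
    n_input_unite: int
    n_matched: int
    n_contigs: int
    n_species: int
    match_rank_histogram: dict[str, int]


class SisBuildError(ValueError):
    pass


def _check_unique_ids(records: Sequence[TaxRecord], label: str) -> None:
    seen: set[str] = set()
    for r in records:
        if r.record_id in seen:
            raise SisBuildError(f"duplicate {label} record id {r.record_id!r}")
        seen.add(r.record_id)


def build_sis(
    unite_records: Sequence[TaxRecord],
    silva_records: Sequence[TaxRecord],
    trim_overlap: int = 0,
) -> tuple[list[SisContig], SisStats]:
    """Merge the two collections into SIS contigs.

    Every ITS record whose lineage matches an 18S reference at some rank
    yields one contig: 18S sequence + ITS sequence, joined by direct
    concatenation.  Unmatched ITS records are counted but excluded.  The
    output is sorted by contig id, so rebuilding from the same inputs is
    byte-reproducible.

    ``trim_overlap=k`` (k >= 1) additionally removes an exact duplication
    at the junction — the longest ITS-record prefix of length >= k that
    equals the 18S suffix — for ITS records that retain trailing 18S bases.
    Default off: the straight concatenation is the reference behaviour.
    """
    if not silva_records:
        raise SisBuildError("cannot build SIS from an empty 18S collection")
    if not unite_records:
        raise SisBuildError("cannot build SIS from an empty ITS collection")
    _check_unique_ids(unite_records, "unite")
    _check_unique_ids(silva_records, "silva")

    index = SilvaNameIndex(silva_records)
    silva_by_id = {r.record_id: r for r in silva_records}

    contigs: list[SisContig] = []
    rank_hist: Counter[str] = Counter()
    n_matched = 0
    for u in unite_records:
        m = match_lowest_level(u.lineage, index)
        if m.silva_id is None:
            continue
        n_matched += 1
        rank_hist[m.match_rank] += 1
        s = silva_by_id[m.silva_id]
        unite_seq = u.sequence
        if trim_overlap >= 1:
            k = _junction_overlap(s.sequence, unite_seq, trim_overlap)
            unite_seq = unite_seq[k:]
            if not unite_seq:
                raise SisBuildError(
                    f"trim-overlap removed the whole ITS record {u.record_id!r}"
                )
        contig_id = f"{u.record_id}|{m.silva_id}|{m.match_rank}"
        contigs.append(
            SisContig(
                contig_id=contig_id,
                sequence=s.sequence + unite_seq,
                join_pos=len(s.sequence),
                unite_id=u.record_id,
                silva_id=m.silva_id,
                match_rank=m.match_rank,
                lineage=u.lineage,
            )
        )
    contigs.sort(key=lambda c: c.contig_id)
    stats = summarize_sis(contigs, n_input_unite=len(unite_records))
    assert stats.n_matched == n_matched
    return contigs, stats


def _junction_overlap(silva_seq: str, unite_seq: str, k_min: int) -> int:
    """Length of the longest ITS prefix (>= k_min) duplicating the 18S suffix."""
    best = 0
    limit = min(len(silva_seq), len(unite_seq) - 1)
    for k in range(k_min, limit + 1):
        if silva_seq.endswith(unite_seq[:k]):
            best = k
    return best


def extract_3prime_window(record: TaxRecord | SisContig, width: int = 250) -> str:
    """The final *width* bases of a sequence — the primer design window
    immediately upstream of ITS1 when applied to an 18S record.

    Shorter sequences are returned whole with a warning.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    seq = record.sequence
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) < width:
        rid = getattr(record, "record_id", None) or getattr(record, "contig_id", "?")
        warnings.warn(
            f"sequence {rid} is {len(seq)} bp, shorter than the "
            f"{width}-bp window; returning the full sequence",
            stacklevel=2,
        )
        return seq
    return seq[-width:]


def summarize_sis(
    contigs: Sequence[SisContig], n_input_unite: int | None = None
) -> SisStats:
    """Database summary: contig count, distinct species (placeholders
    excluded, counted from the fixed-rank ITS-side lineage), and the
    histogram of match ranks."""
    species = {
        c.lineage.name("species")
        for c in contigs
        if not is_placeholder(c.lineage.name("species"))
    }
    hist: Counter[str] = Counter(c.match_rank for c in contigs)
    n = len(contigs)
    return SisStats(
        n_input_unite=n_input_unite if n_input_unite is not None else n,
        n_matched=n,
        n_contigs=n,
        n_species=len(species),
        match_rank_histogram=dict(hist),
    )


# ---------------------------------------------------------------------------
# Persistence: SIS FASTA (provenance header) + TSV sidecar

def write_sis_fasta(contigs: Iterable[SisContig], path: str | Path) -> None:
    """Write contigs as ``>{unite_id}|{silva_id}|{match_rank} {lineage}``."""
    path = Path(path)
    with path.open("w") as fh:
        for c in contigs:
            fh.write(f">{c.contig_id} {c.lineage}\n{c.sequence}\n")


def write_sis_sidecar(contigs: Iterable[SisContig], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("contig_id\tunite_id\tsilva_id\tmatch_rank\tjoin_pos\tlineage\n")
        for c in contigs:
            fh.write(
                f"{c.contig_id}\t{c.unite_id}\t{c.silva_id}\t{c.match_rank}"
                f"\t{c.join_pos}\t{c.lineage}\n"
            )


def read_sis_fasta(fasta_path: str | Path, sidecar_path: str | Path) -> list[SisContig]:
    """Load a SIS database written by :func:`write_sis_fasta` /
    :func:`write_sis_sidecar` (the sidecar supplies join positions)."""
    from Bio import SeqIO

    meta: dict[str, tuple[str, str, str, int]] = {}
    with Path(sidecar_path).open() as fh:
        header = fh.readline()
        for line in fh:
            cid, uid, sid, rank, jp, _lineage = line.rstrip("\n").split("\t")
            meta[cid] = (uid, sid, rank, int(jp))
    contigs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        cid = rec.id
        if cid not in meta:
            raise ValueError(f"contig {cid!r} missing from sidecar")
        lineage_str = rec.description.partition(" ")[2]
        uid, sid, rank, jp = meta[cid]
        contigs.append(
            SisContig(
                contig_id=cid,
                sequence=str(rec.seq).upper(),
                join_pos=jp,
                unite_id=uid,
                silva_id=sid,
                match_rank=rank,
                lineage=parse_lineage(lineage_str, "unite"),
            )
        )
    return contigs
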