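"""Lineage parsing and cross-database taxonomy matching.

Fungal ITS reference collections annotate sequences with lineages in two
incompatible header dialects: a fixed seven-rank form with rank prefixes
(``k__Fungi;p__Ascomycota;...;s__Candida_albicans``, the UNITE convention)
and a variable-depth semicolon list without prefixes (the SILVA convention).
This module parses both into a common :class:`Lineage`, normalizes names so
they compare across dialects, and matches each ITS record to an 18S
reference at the lowest (most specific) taxonomic level at which the two
lineages share a name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

UNITE_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_RANK_PREFIX = re.compile(r"^[kpcofgs]__")
_WS = re.compile(r"\s+")

#: normalized names that denote "no taxon here" and are skipped in matching
_PLACEHOLDER_EXACT = frozenset({"", "unidentified", "unclassified", "uncultured"})


class LineageParseError(ValueError):
    """A lineage string that cannot be parsed under the requested dialect."""

    def __init__(self, header: str, reason: str):
        self.header = header
        self.reason = reason
        super().__init__(f"cannot parse lineage {header!r}: {reason}")


def normalize_name(name_raw: str) -> str:
    """Canonical form of one taxon name: rank prefix stripped, underscores
    to spaces, lowercased, internal whitespace collapsed, trimmed.

    Idempotent: ``normalize_name(normalize_name(x)) == normalize_name(x)``.
    """
    name = _RANK_PREFIX.sub("", name_raw)
    name = name.replace("_", " ")
    name = _WS.sub(" ", name).strip()
    return name.lower()


def is_placeholder(name_norm: str) -> bool:
    """True for names that stand in for missing identification: empty,
    'unidentified'-style labels, and open nomenclature like 'candida sp'."""
    if name_norm in _PLACEHOLDER_EXACT:
        return True
    if name_norm.startswith("unidentified"):
        return True
    if name_norm.endswith(" sp") or name_norm.endswith(" sp."):
        return True
    return False


@dataclass(frozen=True)
class Rank:
    label: str
    name_raw: str
    name_norm: str


@dataclass(frozen=True)
class Lineage:
    """An ordered list of taxonomic names.

    ``unite`` dialect lineages always carry exactly seven ranks (kingdom
    through species; missing ranks are explicit placeholders). ``silva``
    dialect lineages have one or more ranks of arbitrary depth, labelled
    positionally (``level_1`` ...).
    """

    ranks: tuple[Rank, ...]
    dialect: str

    def __post_init__(self) -> None:
        if self.dialect not in ("unite", "silva"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.dialect == "unite" and len(self.ranks) != len(UNITE_RANKS):
            raise ValueError("unite lineage must have exactly 7 ranks")
        if self.dialect == "silva" and not self.ranks:
            raise ValueError("silva lineage must have >= 1 ranks")

    def name(self, rank_label: str) -> str:
        """Normalized name at *rank_label* (unite lineages only)."""
        for r in self.ranks:
            if r.label == rank_label:
                return r.name_norm
        raise KeyError(rank_label)

    @property
    def names_norm(self) -> tuple[str, ...]:
        return tuple(r.name_norm for r in self.ranks)

    def __str__(self) -> str:
        return ";".join(r.name_raw for r in self.ranks)


def parse_lineage(header: str, dialect: str) -> Lineage:
    """Parse a semicolon-delimited lineage string under *dialect*.

    unite: exactly seven ``x__Name`` fields in kingdom..species order;
    fields that are empty after the prefix become 'unidentified'
    placeholders (kept, never dropped).  silva: any positive number of
    plain names.
    """
    if not header or not header.strip():
        raise LineageParseError(header, "empty lineage string")
    parts = [p.strip() for p in header.strip().strip(";").split(";")]
    if dialect == "unite":
        if len(parts) != len(UNITE_RANKS):
            raise LineageParseError(
                header, f"expected 7 semicolon fields, got {len(parts)}"
            )
        ranks = []
        for label, raw in zip(UNITE_RANKS, parts):
            norm = normalize_name(raw)
            if norm == "":
                raw, norm = "unidentified", "unidentified"
            ranks.append(Rank(label, raw, norm))
        return Lineage(tuple(ranks), "unite")
    if dialect == "silva":
        parts = [p for p in parts if p != ""]
        if not parts:
            raise LineageParseError(header, "no nonempty fields")
        ranks = tuple(
            Rank(f"level_{i + 1}", raw, normalize_name(raw))
            for i, raw in enumerate(parts)
        )
        return Lineage(ranks, "silva")
    raise ValueError(f"unknown dialect {dialect!r}")


@dataclass(frozen=True)
class TaxRecord:
    """One reference sequence with its parsed lineage."""

    record_id: str
    sequence: str
    lineage: Lineage
    source: str  # "silva" | "unite"

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be nonempty")
        if not self.sequence:
            raise ValueError(f"record {self.record_id}: empty sequence")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one ITS record against the 18S collection.

    ``silva_id`` is None exactly when ``match_rank`` is None (no rank of
    the query lineage names a taxon present in any reference lineage).
    """

    unite_id: str
    silva_id: str | None
    match_rank: str | None

    def __post_init__(self) -> None:
        if (self.silva_id is None) != (self.match_rank is None):
            raise ValueError("silva_id is None iff match_rank is None")


class SilvaNameIndex:
    """Inverted index: normalized taxon name -> sorted reference ids.

    Built once per reference collection; lookup is O(1) per rank, so
    matching a full ITS collection is linear in its size.
    """

    def __init__(self, silva_records: Iterable[TaxRecord]):
        by_name: dict[str, set[str]] = {}
        n = 0
        for rec in silva_records:
            n += 1
            for name in rec.lineage.names_norm:
                by_name.setdefault(name, set()).add(rec.record_id)
        self._by_name: Mapping[str, tuple[str, ...]] = {
            name: tuple(sorted(ids)) for name, ids in by_name.items()
        }
        self.n_records = n

    def lookup(self, name_norm: str) -> tuple[str, ...]:
        return self._by_name.get(name_norm, ())


def match_lowest_level(
    unite_lineage: Lineage,
    silva_index: SilvaNameIndex | Iterable[TaxRecord],
) -> MatchResult | None:
    """Match a seven-rank lineage to the reference collection at the lowest
    possible taxonomic level.

    Ranks are tried from species up to kingdom; placeholder names
    ('unidentified', 'xxx sp', empty) are skipped.  A rank matches when its
    normalized name equals, as a whole name, a normalized name anywhere in a
    reference lineage — substring hits (e.g. 'candida' inside 'candidatus')
    never count.  Ties among references at the winning rank go to the
    lexicographically smallest record id, which makes the result independent
    of collection order.

    Returns a :class:`MatchResult` with ``unite_id=""`` (the caller fills in
    the id); returns the none-result when no rank matches.
    """
    if unite_lineage.dialect != "unite":
        raise ValueError("query lineage must be unite dialect")
    if not isinstance(silva_index, SilvaNameIndex):
        silva_index = SilvaNameIndex(silva_index)
    for rank in reversed(unite_lineage.ranks):  # species -> kingdom
        if is_placeholder(rank.name_norm):
            continue
        candidates = silva_index.lookup(rank.name_norm)
        if candidates:
            return MatchResult("", candidates[0], rank.label)
    return MatchResult("", None, None)


# ---------------------------------------------------------------------------
# FASTA reading

def detect_dialect(description: str) -> str:
    """'unite' when the header carries rank prefixes (``k__``), else 'silva'."""
    return "unite" if "k__" in description else "silva"


def _split_header(description: str, dialect: str) -> tuple[str, str]:
    """Split a FASTA description into (record_id, lineage string)."""
    if dialect == "unite":
        # UNITE headers delimit id and lineage with '|' or whitespace
        if "|" in description.split("k__")[0]:
            idpart, _, rest = description.partition("|")
            # lineage may itself contain '|'-separated metadata before k__
            kpos = rest.find("k__")
            if kpos < 0:
                raise LineageParseError(description, "no k__ field in unite header")
            return idpart.strip(), rest[kpos:]
        idpart, _, rest = description.partition(" ")
        return idpart.strip(), rest.strip()
    idpart, _, rest = description.partition(" ")
    return idpart.strip(), rest.strip()


def read_fasta(path: str | Path, dialect: str | None = None) -> list[TaxRecord]:
    """Read a lineage-annotated FASTA file into :class:`TaxRecord` objects.

    *dialect* is auto-detected per file (presence of ``k__`` in the first
    header) when not given.  Sequences are uppercased; U is read as T.
    Duplicate record ids raise ``ValueError``.
    """
    path = Path(path)
    records: list[TaxRecord] = []
    seen: set[str] = set()
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        desc = seq_rec.description
        d = dialect or detect_dialect(desc)
        record_id, lineage_str = _split_header(desc, d)
        lineage = parse_lineage(lineage_str, d)
        if record_id in seen:
            raise ValueError(f"duplicate record id {record_id!r} in {path}")
        seen.add(record_id)
        seq = str(seq_rec.seq).upper().replace("U", "T")
        records.append(TaxRecord(record_id, seq, lineage, d))
    return records
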