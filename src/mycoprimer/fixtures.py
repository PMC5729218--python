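"""Deterministic synthetic reference collections with planted ground truth.

Real primer evaluation needs two taxonomy-annotated FASTA collections (an
18S collection in the variable-depth lineage dialect and an ITS collection
in the fixed seven-rank dialect).  This generator emulates both at desk
scale: background sequences are random, but each record carries a *planted*
primer binding site with a requested number of mismatches at known
positions, and lineages are constructed so that every record matches the
18S collection at exactly the requested rank (or not at all).  A manifest
records the coordinates, scores and amplicon lengths every downstream stage
must reproduce, which makes the whole pipeline testable without downloads.

Geometry: the forward site is planted as the final bases of the 18S record
(inside the 3' design window), so the predicted amplicon length is
controlled entirely by where the reverse site is planted in the ITS record.

Determinism: one seeded PCG64 generator drives all randomness; the same
spec and seed reproduce byte-identical FASTA and manifest files on any
platform.  A rejection step redraws background segments that would by
chance out-score a planted site, so the planted truth is the unique truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import iupac
from .insilico_pcr import (
    DEFAULT_AMP_HARD_MAX,
    DEFAULT_SCORE_THRESHOLD,
    THREE_PRIME_LEN,
    WEIGHT_3,
    WEIGHT_LAST,
    WEIGHT_NON3,
    AmpliconPrediction,
    CoverageReport,
    _scan_scores,
)
from .sisdb import SisContig, SisStats
from .taxonomy import UNITE_RANKS, TaxRecord, normalize_name, parse_lineage
from .thermo import Oligo


class InfeasiblePlanError(ValueError):
    """The requested fixture plan cannot be realized exactly."""


class FixtureVerificationError(ValueError):
    """Pipeline outputs and manifest describe different record universes."""


@dataclass(frozen=True)
class PlantPlan:
    """Planted-site request for one ITS record.

    ``fwd_mismatches`` fills the forward site's non-3' region first, then
    the 3' region; the terminal base is controlled separately by
    ``fwd_terminal_mismatch``.  ``rev_mismatches`` fills non-3', then 3',
    then the terminal base last.  ``amplicon_length`` is the exact product
    length the planted pair will produce.
    """

    fwd_mismatches: int = 0
    fwd_terminal_mismatch: bool = False
    rev_mismatches: int = 0
    amplicon_length: int = 400


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic fixture.

    ``silva_match_plan[i]`` is the rank at which ITS record *i* must match
    the 18S collection (None = no match anywhere); ``plant_plan[i]`` is the
    planted-site request (None = no sites planted, the record cannot
    amplify).  Nine phyla mirror the phylum panel a coverage heat map
    reports on; 18S lengths are full-gene scale and ITS lengths span the
    typical ITS1+5.8S range.
    """

    n_phyla: int
    n_species: int
    n_unite_records: int
    silva_match_plan: tuple[str | None, ...]
    plant_plan: tuple[PlantPlan | None, ...]
    its1_length_range: tuple[int, int] = (400, 700)
    silva_length_range: tuple[int, int] = (1600, 1800)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.silva_match_plan) != self.n_unite_records:
            raise InfeasiblePlanError("silva_match_plan length != n_unite_records")
        if len(self.plant_plan) != self.n_unite_records:
            raise InfeasiblePlanError("plant_plan length != n_unite_records")
        for r in self.silva_match_plan:
            if r is not None and r not in UNITE_RANKS:
                raise InfeasiblePlanError(f"unknown rank {r!r} in match plan")
        if not (1 <= self.n_species and 1 <= self.n_phyla):
            raise InfeasiblePlanError("need >= 1 phylum and species")


@dataclass(frozen=True)
class RecordTruth:
    """Ground truth for one ITS record after the pipeline runs."""

    unite_id: str
    lineage: str
    match_rank: str | None
    silva_id: str | None
    fwd_start: int | None
    fwd_end: int | None
    fwd_score: float | None
    rev_start: int | None
    rev_end: int | None
    rev_score: float | None
    amplicon_length: int | None
    is_hit: bool


@dataclass(frozen=True)
class FixtureManifest:
    """Per-record planted truth plus the aggregates they imply."""

    records: tuple[RecordTruth, ...]
    n_input_unite: int
    n_matched: int
    n_species: int
    match_rank_histogram: dict[str, int]
    score_threshold: float
    per_phylum: dict[str, tuple[int, int]]  # phylum -> (n_records, n_hits)
    overall: tuple[int, int]

    def to_json(self) -> str:
        payload = {
            "records": [asdict(r) for r in self.records],
            "n_input_unite": self.n_input_unite,
            "n_matched": self.n_matched,
            "n_species": self.n_species,
            "match_rank_histogram": self.match_rank_histogram,
            "score_threshold": self.score_threshold,
            "per_phylum": {k: list(v) for k, v in self.per_phylum.items()},
            "overall": list(self.overall),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureManifest":
        d = json.loads(text)
        return cls(
            records=tuple(RecordTruth(**r) for r in d["records"]),
            n_input_unite=d["n_input_unite"],
            n_matched=d["n_matched"],
            n_species=d["n_species"],
            match_rank_histogram=d["match_rank_histogram"],
            score_threshold=d["score_threshold"],
            per_phylum={k: tuple(v) for k, v in d["per_phylum"].items()},
            overall=tuple(d["overall"]),
        )


@dataclass(frozen=True)
class Fixture:
    """In-memory fixture: the two collections plus the manifest."""

    silva_records: tuple[TaxRecord, ...]
    unite_records: tuple[TaxRecord, ...]
    manifest: FixtureManifest

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write silva.fasta, unite.fasta and manifest.json (deterministic
        bytes for a given spec and seed)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        silva_path = outdir / "silva.fasta"
        unite_path = outdir / "unite.fasta"
        manifest_path = outdir / "manifest.json"
        with silva_path.open("w") as fh:
            for r in self.silva_records:
                fh.write(f">{r.record_id} {r.lineage}\n{r.sequence}\n")
        with unite_path.open("w") as fh:
            for r in self.unite_records:
                fh.write(f">{r.record_id}|{r.lineage}\n{r.sequence}\n")
        manifest_path.write_text(self.manifest.to_json() + "\n")
        return {"silva": silva_path, "unite": unite_path, "manifest": manifest_path}


# ---------------------------------------------------------------------------
# lineage construction

_RANK_PREFIXES = dict(zip(UNITE_RANKS, ("k", "p", "c", "o", "f", "g", "s")))


def _unite_names(i: int, sp: int, phy: int, matched: bool) -> dict[str, str]:
    """Raw rank names for ITS record *i* (species index sp, phylum phy).

    Matched records share the standard kingdom and per-phylum /
    per-species names; unmatched records get globally unique names at every
    rank so no rank can collide with any 18S lineage.
    """
    if matched:
        return {
            "kingdom": "Fungi",
            "phylum": f"Phylum{phy:02d}",
            "class": f"Classis{phy:02d}",
            "order": f"Ordo{phy:02d}",
            "family": f"Familia{sp:03d}",
            "genus": f"Genus{sp:03d}",
            "species": f"Genus{sp:03d}_specius{sp:03d}",
        }
    return {
        "kingdom": f"Regnumx{i:03d}",
        "phylum": f"Phylumx{i:03d}",
        "class": f"Classisx{i:03d}",
        "order": f"Ordox{i:03d}",
        "family": f"Familiax{i:03d}",
        "genus": f"Genusx{i:03d}",
        "species": f"Genusx{i:03d}_speciusx{i:03d}",
    }


def _unite_lineage_str(names: Mapping[str, str]) -> str:
    return ";".join(f"{_RANK_PREFIXES[r]}__{names[r]}" for r in UNITE_RANKS)


def _silva_lineage_str(names: Mapping[str, str], down_to: str) -> str:
    """Variable-depth lineage sharing the ITS names from kingdom down to
    *down_to*, with species rendered in space form."""
    idx = UNITE_RANKS.index(down_to)
    parts = ["Eukaryota"]
    for r in UNITE_RANKS[: idx + 1]:
        parts.append(names[r].replace("_", " "))
    return ";".join(parts)


# ---------------------------------------------------------------------------
# planted-site construction

def _concrete(primer: str) -> str:
    """A deterministic concrete realization of a degenerate primer
    (alphabetically first base of each expansion set)."""
    return "".join(min(iupac.expansion(ch)) for ch in primer)


def _mismatch_base(primer_base: str) -> str:
    """Alphabetically first concrete base outside the expansion set."""
    for b in "ACGT":
        if b not in iupac.expansion(primer_base):
            return b
    raise InfeasiblePlanError("cannot place a mismatch against an N position")


def _planted_target(
    primer: str, n_mismatch: int, terminal_mismatch: bool
) -> tuple[str, float]:
    """Primer-oriented target carrying the requested mismatches.

    Non-3' positions (left to right) are consumed first, then the four 3'
    positions, then — only if the count still exceeds capacity — the
    terminal base; ``terminal_mismatch`` forces the terminal base
    regardless.  Returns (target 5'->3' in primer orientation, score).
    """
    n = len(primer)
    non3 = list(range(0, max(n - THREE_PRIME_LEN, 0)))
    three = list(range(max(n - THREE_PRIME_LEN, 0), n - 1))
    order = non3 + three
    if n_mismatch > len(order) + (not terminal_mismatch):
        raise InfeasiblePlanError(
            f"{n_mismatch} mismatches exceed primer capacity ({n} bases)"
        )
    target = list(_concrete(primer))
    n_non3 = n_3 = 0
    last = terminal_mismatch
    remaining = n_mismatch
    for pos in order:
        if remaining == 0:
            break
        target[pos] = _mismatch_base(primer[pos])
        if pos in three:
            n_3 += 1
        else:
            n_non3 += 1
        remaining -= 1
    if remaining > 0:  # spill into the terminal base
        last = True
        remaining -= 1
    if last:
        target[n - 1] = _mismatch_base(primer[n - 1])
    score = (
        round(WEIGHT_NON3 * 10) * n_non3
        + round(WEIGHT_3 * 10) * n_3
        + round(WEIGHT_LAST * 10) * last
    ) / 10.0
    return "".join(target), score


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# the generator

_MAX_REDRAWS = 100


def make_fixture(spec: FixtureSpec, fwd: Oligo, rev: Oligo) -> Fixture:
    """Generate the two FASTA collections and the ground-truth manifest.

    Raises :class:`InfeasiblePlanError` before anything is produced when
    the plan cannot be realized exactly (amplicon shorter than the two
    primer footprints, mismatch counts exceeding primer length, taxonomy
    sharing that would force a deeper match than requested, or an ITS
    length range too short for a requested amplicon).
    """
    rng = np.random.default_rng(spec.seed)
    lf, lr = len(fwd.sequence), len(rev.sequence)
    n = spec.n_unite_records

    # ---- taxonomy bookkeeping (closed form, validated) ----
    sp_idx = [i % spec.n_species for i in range(n)]
    phy_idx = [s % spec.n_phyla for s in sp_idx]
    names = [
        _unite_names(i, sp_idx[i], phy_idx[i], spec.silva_match_plan[i] is not None)
        for i in range(n)
    ]
    # exposure: normalized name -> sorted silva ids exposing it
    silva_id_of = {
        i: f"SLV{i:04d}" for i in range(n) if spec.silva_match_plan[i] is not None
    }
    exposed: dict[str, list[str]] = {}
    for i, sid in silva_id_of.items():
        down_to = spec.silva_match_plan[i]
        for r in UNITE_RANKS[: UNITE_RANKS.index(down_to) + 1]:
            exposed.setdefault(normalize_name(names[i][r]), []).append(sid)
    exposed = {k: sorted(v) for k, v in exposed.items()}
    owner_of_silva = {sid: i for i, sid in silva_id_of.items()}

    expected_rank: list[str | None] = []
    expected_silva: list[str | None] = []
    for i in range(n):
        rank_found = None
        sid_found = None
        for r in reversed(UNITE_RANKS):  # species -> kingdom
            ids = exposed.get(normalize_name(names[i][r]))
            if ids:
                rank_found, sid_found = r, ids[0]
                break
        if rank_found != spec.silva_match_plan[i]:
            raise InfeasiblePlanError(
                f"record {i}: name sharing forces match at rank {rank_found!r} "
                f"but plan requests {spec.silva_match_plan[i]!r}"
            )
        expected_rank.append(rank_found)
        expected_silva.append(sid_found)
        if sid_found is not None:
            owner = owner_of_silva[sid_found]
            if spec.plant_plan[owner] is None:
                same_fwd = spec.plant_plan[i] is None
            elif spec.plant_plan[i] is None:
                same_fwd = False
            else:
                a, b = spec.plant_plan[owner], spec.plant_plan[i]
                same_fwd = (
                    a.fwd_mismatches == b.fwd_mismatches
                    and a.fwd_terminal_mismatch == b.fwd_terminal_mismatch
                )
            if not same_fwd:
                raise InfeasiblePlanError(
                    f"record {i}: matches 18S record of record {owner}, whose "
                    "forward-site plant differs; make the plans agree"
                )

    # ---- geometry feasibility ----
    for i, plan in enumerate(spec.plant_plan):
        if plan is None or spec.silva_match_plan[i] is None:
            continue
        if plan.amplicon_length < lf + lr:
            raise InfeasiblePlanError(
                f"record {i}: amplicon {plan.amplicon_length} shorter than the "
                f"primer footprints ({lf}+{lr})"
            )
        if plan.amplicon_length - lf > spec.its1_length_range[1]:
            raise InfeasiblePlanError(
                f"record {i}: amplicon {plan.amplicon_length} needs an ITS "
                f"record longer than its1_length_range allows"
            )

    # ---- sequence construction ----
    silva_records: list[TaxRecord] = []
    unite_records: list[TaxRecord] = []
    truths: list[RecordTruth] = []
    # per silva id: (length, fwd score of the planted site or None)
    silva_geom: dict[str, tuple[int, float | None]] = {}
    silva_seq_of: dict[str, str] = {}
    unite_seq_of: dict[str, str] = {}

    guard = DEFAULT_SCORE_THRESHOLD

    for i in range(n):
        matched = spec.silva_match_plan[i] is not None
        plan = spec.plant_plan[i]
        lineage_str = _unite_lineage_str(names[i])

        # dedicated 18S record for matched ITS records
        if matched:
            sid = silva_id_of[i]
            l18 = int(rng.integers(*spec.silva_length_range, endpoint=True))
            if plan is not None:
                fwd_target, fwd_score = _planted_target(
                    fwd.sequence, plan.fwd_mismatches, plan.fwd_terminal_mismatch
                )
            else:
                fwd_target, fwd_score = None, None
            silva_seq = _draw_guarded(
                rng, l18, fwd, rev,
                plant=fwd_target, plant_at=l18 - lf if fwd_target else None,
                plant_for="fwd", guard=guard, guard_floor=fwd_score,
            )
            silva_records.append(
                TaxRecord(
                    sid,
                    silva_seq,
                    parse_lineage(
                        _silva_lineage_str(names[i], spec.silva_match_plan[i]),
                        "silva",
                    ),
                    "silva",
                )
            )
            silva_geom[sid] = (l18, fwd_score)
            silva_seq_of[sid] = silva_seq

        # the ITS record
        uid = f"UNT{i:04d}"
        if matched and plan is not None:
            min_its = max(spec.its1_length_range[0], plan.amplicon_length - lf)
            l_its = int(rng.integers(min_its, spec.its1_length_range[1], endpoint=True))
            rev_target, rev_score = _planted_target(
                rev.sequence, plan.rev_mismatches, False
            )
            rev_window = iupac.revcomp(rev_target)  # plus-strand text
            rev_end_off = plan.amplicon_length - lf
            unite_seq = _draw_guarded(
                rng, l_its, fwd, rev,
                plant=rev_window, plant_at=rev_end_off - lr,
                plant_for="rev", guard=guard, guard_floor=rev_score,
            )
        else:
            l_its = int(rng.integers(*spec.its1_length_range, endpoint=True))
            unite_seq = _draw_guarded(
                rng, l_its, fwd, rev, plant=None, plant_at=None,
                plant_for=None, guard=guard, guard_floor=None,
            )
            rev_score = None
        unite_records.append(
            TaxRecord(uid, unite_seq, parse_lineage(lineage_str, "unite"), "unite")
        )
        unite_seq_of[uid] = unite_seq

        # ---- ground truth row ----
        if matched:
            sid_matched = expected_silva[i]
            l18_m, fwd_score_m = silva_geom.get(sid_matched, (None, None))
            # matched silva record may belong to a later record; fill in pass 2
            truths.append(
                RecordTruth(
                    unite_id=uid,
                    lineage=lineage_str,
                    match_rank=expected_rank[i],
                    silva_id=sid_matched,
                    fwd_start=None, fwd_end=None, fwd_score=None,
                    rev_start=None, rev_end=None, rev_score=rev_score,
                    amplicon_length=None,
                    is_hit=False,
                )
            )
        else:
            truths.append(
                RecordTruth(
                    unite_id=uid, lineage=lineage_str,
                    match_rank=None, silva_id=None,
                    fwd_start=None, fwd_end=None, fwd_score=None,
                    rev_start=None, rev_end=None, rev_score=None,
                    amplicon_length=None, is_hit=False,
                )
            )

    # ---- pass 2: resolve coordinates now every 18S record exists ----
    final_truths: list[RecordTruth] = []
    for i, t in enumerate(truths):
        plan = spec.plant_plan[i]
        if t.silva_id is None or plan is None:
            if t.silva_id is not None:
                _assert_contig_clean(
                    silva_seq_of[t.silva_id] + unite_seq_of[t.unite_id],
                    fwd, rev, None, None, None, None, guard,
                )
            final_truths.append(t)
            continue
        l18, fwd_score = silva_geom[t.silva_id]
        a = plan.amplicon_length
        rev_end = l18 - lf + a
        rev_start = rev_end - lr
        _assert_contig_clean(
            silva_seq_of[t.silva_id] + unite_seq_of[t.unite_id],
            fwd, rev, l18 - lf, fwd_score, rev_start, t.rev_score, guard,
        )
        hit = (
            fwd_score is not None
            and fwd_score <= DEFAULT_SCORE_THRESHOLD
            and t.rev_score is not None
            and t.rev_score <= DEFAULT_SCORE_THRESHOLD
            and a <= DEFAULT_AMP_HARD_MAX
        )
        final_truths.append(
            RecordTruth(
                unite_id=t.unite_id, lineage=t.lineage,
                match_rank=t.match_rank, silva_id=t.silva_id,
                fwd_start=l18 - lf, fwd_end=l18, fwd_score=fwd_score,
                rev_start=rev_start, rev_end=rev_end, rev_score=t.rev_score,
                amplicon_length=a, is_hit=hit,
            )
        )

    manifest = _build_manifest(spec, names, sp_idx, phy_idx, final_truths)
    return Fixture(tuple(silva_records), tuple(unite_records), manifest)


def _draw_guarded(
    rng: np.random.Generator,
    length: int,
    fwd: Oligo,
    rev: Oligo,
    plant: str | None,
    plant_at: int | None,
    plant_for: str | None,
    guard: float,
    guard_floor: float | None,
) -> str:
    """Random sequence of *length* with an optional planted window, redrawn
    until no background offset scores <= max(guard, planted score) for the
    forward primer (plus strand) or reverse primer (minus strand)."""
    if plant is not None:
        if plant_at is None or plant_at < 0 or plant_at + len(plant) > length:
            raise InfeasiblePlanError(
                f"planted window [{plant_at}, ...) does not fit in {length} bases"
            )
    level = guard if guard_floor is None else max(guard, guard_floor)
    for _ in range(_MAX_REDRAWS):
        seq = _random_dna(rng, length)
        if plant is not None:
            seq = seq[:plant_at] + plant + seq[plant_at + len(plant):]
        if _background_clean(seq, fwd, rev, plant_at, plant_for, level):
            return seq
    raise InfeasiblePlanError(
        "could not draw a background free of accidental primer sites"
    )


def _background_clean(
    seq: str,
    fwd: Oligo,
    rev: Oligo,
    plant_at: int | None,
    plant_for: str | None,
    level: float,
) -> bool:
    """True when every non-planted offset scores strictly above *level*
    for both primers in their search orientations."""
    for which, oriented in (("fwd", fwd.sequence), ("rev", iupac.revcomp(rev.sequence))):
        scores = _scan_scores(oriented, seq, three_prime_left=(which == "rev"))
        if scores.size == 0:
            continue
        if plant_at is not None and plant_for == which and plant_at < scores.size:
            scores = np.delete(scores, plant_at)
        if scores.size and scores.min() <= level:
            return False
    return True


def _assert_contig_clean(
    contig_seq: str,
    fwd: Oligo,
    rev: Oligo,
    fwd_at: int | None,
    fwd_score: float | None,
    rev_at: int | None,
    rev_score: float | None,
    guard: float,
) -> None:
    """Final junction-spanning check on an assembled contig: the planted
    offsets must be the unique best sites and every other offset must stay
    above the guard level.  Per-part redraws cannot see windows that
    straddle the 18S/ITS junction, so this closes that gap (a breach is
    astronomically unlikely; it raises rather than emitting a wrong truth).
    """
    for which, oriented, at, sc in (
        ("fwd", fwd.sequence, fwd_at, fwd_score),
        ("rev", iupac.revcomp(rev.sequence), rev_at, rev_score),
    ):
        scores = _scan_scores(oriented, contig_seq, three_prime_left=(which == "rev"))
        level = guard if sc is None else max(guard, sc)
        if at is not None:
            if not np.isclose(scores[at], sc):
                raise InfeasiblePlanError(
                    f"planted {which} site scores {scores[at]}, plan says {sc}"
                )
            scores = np.delete(scores, at)
        if scores.size and scores.min() <= level:
            raise InfeasiblePlanError(
                f"accidental {which} site at the 18S/ITS junction "
                f"(score {scores.min():.2f}); use a different seed"
            )


def _build_manifest(
    spec: FixtureSpec,
    names: Sequence[Mapping[str, str]],
    sp_idx: Sequence[int],
    phy_idx: Sequence[int],
    truths: Sequence[RecordTruth],
) -> FixtureManifest:
    n_matched = sum(t.match_rank is not None for t in truths)
    species = {
        normalize_name(names[i]["species"])
        for i, t in enumerate(truths)
        if t.match_rank is not None
    }
    hist: dict[str, int] = {}
    for t in truths:
        if t.match_rank:
            hist[t.match_rank] = hist.get(t.match_rank, 0) + 1
    per_phylum: dict[str, list[int]] = {}
    n_hits = 0
    for i, t in enumerate(truths):
        if t.match_rank is None:
            continue
        phylum = normalize_name(names[i]["phylum"])
        row = per_phylum.setdefault(phylum, [0, 0])
        row[0] += 1
        row[1] += int(t.is_hit)
        n_hits += int(t.is_hit)
    return FixtureManifest(
        records=tuple(truths),
        n_input_unite=spec.n_unite_records,
        n_matched=n_matched,
        n_species=len(species),
        match_rank_histogram=hist,
        score_threshold=DEFAULT_SCORE_THRESHOLD,
        per_phylum={k: (v[0], v[1]) for k, v in sorted(per_phylum.items())},
        overall=(n_matched, n_hits),
    )


# ---------------------------------------------------------------------------
# convenience plans

def coverage_spec(
    n_records: int = 50,
    target_coverage: float = 0.8,
    n_phyla: int = 9,
    n_species: int | None = None,
    seed: int = 0,
    amplicon_length: int = 400,
    n_unmatched: int = 0,
) -> FixtureSpec:
    """A spec whose expected overall coverage is exactly *target_coverage*.

    The first ``round(n_matched * target_coverage)`` matched records get
    perfect planted sites; the rest get three non-3' forward mismatches
    (score 1.2, above the 1.0 hit threshold).  All matches are planted at
    species rank with one 18S record each, so the plan is always feasible.
    """
    n_matched = n_records - n_unmatched
    if n_matched < 0:
        raise InfeasiblePlanError("n_unmatched exceeds n_records")
    n_hit = round(n_matched * target_coverage)
    match_plan: list[str | None] = ["species"] * n_matched + [None] * n_unmatched
    plant: list[PlantPlan | None] = []
    for i in range(n_records):
        if i >= n_matched:
            plant.append(None)
        elif i < n_hit:
            plant.append(PlantPlan(amplicon_length=amplicon_length))
        else:
            plant.append(PlantPlan(fwd_mismatches=3, amplicon_length=amplicon_length))
    return FixtureSpec(
        n_phyla=n_phyla,
        n_species=n_species if n_species is not None else n_records,
        n_unite_records=n_records,
        silva_match_plan=tuple(match_plan),
        plant_plan=tuple(plant),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# verification

@dataclass(frozen=True)
class VerificationReport:
    passed: bool
    n_compared: int
    first_divergence: str | None


def verify_fixture(
    manifest: FixtureManifest,
    contigs: Sequence[SisContig],
    stats: SisStats,
    predictions: Mapping[str, AmpliconPrediction | None],
    coverage: CoverageReport,
) -> VerificationReport:
    """Compare pipeline outputs against the manifest; stop at the first
    divergence.

    *predictions* maps unite record id -> amplicon prediction (or None).
    Raises :class:`FixtureVerificationError` when the contigs cover a
    different set of ITS records than the manifest expects.
    """
    expected_ids = {t.unite_id for t in manifest.records if t.match_rank is not None}
    got_ids = {c.unite_id for c in contigs}
    if expected_ids != got_ids:
        raise FixtureVerificationError(
            f"record universes differ: manifest has {len(expected_ids)} matched "
            f"records, outputs have {len(got_ids)}; "
            f"missing={sorted(expected_ids - got_ids)[:3]} "
            f"extra={sorted(got_ids - expected_ids)[:3]}"
        )

    n = 0

    def fail(msg: str) -> VerificationReport:
        return VerificationReport(False, n, msg)

    for field_name, got, want in (
        ("n_matched", stats.n_matched, manifest.n_matched),
        ("n_contigs", stats.n_contigs, manifest.n_matched),
        ("n_species", stats.n_species, manifest.n_species),
        ("n_input_unite", stats.n_input_unite, manifest.n_input_unite),
    ):
        n += 1
        if got != want:
            return fail(f"stats.{field_name}: got {got}, manifest says {want}")
    n += 1
    if stats.match_rank_histogram != manifest.match_rank_histogram:
        return fail(
            f"match_rank_histogram: got {stats.match_rank_histogram}, "
            f"manifest says {manifest.match_rank_histogram}"
        )

    by_unite = {c.unite_id: c for c in contigs}
    for t in manifest.records:
        if t.match_rank is None:
            continue
        c = by_unite[t.unite_id]
        n += 1
        if c.match_rank != t.match_rank or c.silva_id != t.silva_id:
            return fail(
                f"{t.unite_id}: matched ({c.silva_id}, {c.match_rank}), "
                f"manifest says ({t.silva_id}, {t.match_rank})"
            )
        amp = predictions.get(t.unite_id)
        if t.amplicon_length is None:
            continue  # nothing planted; best sites are unconstrained background
        n += 1
        if amp is None:
            return fail(f"{t.unite_id}: no amplicon predicted, manifest plants one")
        checks = (
            ("fwd_start", amp.fwd_site.start, t.fwd_start),
            ("fwd_end", amp.fwd_site.end, t.fwd_end),
            ("fwd_score", amp.fwd_site.score, t.fwd_score),
            ("rev_start", amp.rev_site.start, t.rev_start),
            ("rev_end", amp.rev_site.end, t.rev_end),
            ("rev_score", amp.rev_site.score, t.rev_score),
            ("amplicon_length", amp.length, t.amplicon_length),
        )
        for what, got, want in checks:
            n += 1
            if got != want:
                return fail(f"{t.unite_id}: {what} got {got}, manifest says {want}")

    for phylum, (n_rec, n_hit) in manifest.per_phylum.items():
        n += 1
        grp = coverage.per_group.get(phylum)
        if grp is None or (grp.n_records, grp.n_hits) != (n_rec, n_hit):
            got = None if grp is None else (grp.n_records, grp.n_hits)
            return fail(
                f"phylum {phylum!r}: coverage got {got}, manifest says "
                f"({n_rec}, {n_hit})"
            )
    n += 1
    if (coverage.overall.n_records, coverage.overall.n_hits) != manifest.overall:
        return fail(
            f"overall coverage: got ({coverage.overall.n_records}, "
            f"{coverage.overall.n_hits}), manifest says {manifest.overall}"
        )
    return VerificationReport(True, n, None)
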