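import numpy as np
import pytest

from mycoprimer import build_sis, coverage_spec, make_fixture, parse_lineage
from mycoprimer.catalog import primer
from mycoprimer.sisdb import SisContig


@pytest.fixture(scope="session")
def fwd30():
    return primer("ITS1-30F")


@pytest.fixture(scope="session")
def rev217():
    return primer("ITS1-217R")


@pytest.fixture(scope="session")
def fwd48():
    return primer("ITS1-48F")


@pytest.fixture(scope="session")
def small_fixture(fwd30, rev217):
    """12 ITS records: 7 perfect plants, 3 with failing forward sites,
    2 unmatched — expected coverage 7/10 at threshold 1.0."""
    spec = coverage_spec(
        n_records=12, target_coverage=0.7, n_phyla=3, seed=11, n_unmatched=2
    )
    return make_fixture(spec, fwd30, rev217)


@pytest.fixture(scope="session")
def small_sis(small_fixture):
    contigs, stats = build_sis(
        small_fixture.unite_records, small_fixture.silva_records
    )
    return contigs, stats


_LINEAGE = parse_lineage(
    "k__Fungi;p__Ascomycota;c__Saccharomycetes;o__Saccharomycetales;"
    "f__Saccharomycetaceae;g__Candida;s__Candida_albicans",
    "unite",
)


def make_contig(sequence: str, contig_id: str = "c1", join_pos: int | None = None,
                lineage=_LINEAGE) -> SisContig:
    """A bare contig for scorer-level tests (join position is irrelevant
    to binding-site search, so any interior value works)."""
    if join_pos is None:
        join_pos = max(1, len(sequence) // 2)
    return SisContig(
        contig_id=contig_id,
        sequence=sequence,
        join_pos=join_pos,
        unite_id="u1",
        silva_id="s1",
        match_rank="species",
        lineage=lineage,
    )


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
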