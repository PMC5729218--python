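import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycoprimer.insilico_pcr import (
    amplicon_stats,
    evaluate_coverage,
    find_best_site,
    predict_amplicon,
    revcomp,
    score_site,
)
from mycoprimer.iupac import InvalidBaseError
from mycoprimer import build_sis, coverage_spec, make_fixture
from mycoprimer.fixtures import FixtureSpec, PlantPlan

from conftest import make_contig, random_dna

iupac_text = st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=40)


class TestRevcomp:
    @pytest.mark.parametrize("seq,expected", [("ACGT", "ACGT"), ("AAGR", "YCTT"),
                                              ("SWN", "NWS")])
    def test_examples(self, seq, expected):
        assert revcomp(seq) == expected

    @given(iupac_text)
    @settings(max_examples=150, deadline=None)
    def test_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq

    def test_invalid_character(self):
        with pytest.raises(InvalidBaseError):
            revcomp("ACGU")


# --- independent naive scorer (oracle) --------------------------------------

_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}
_COMP = dict(zip("ACGTRYSWKMBDHVN", "TGCAYRSWMKVBHDN"))


def naive_score(primer, window):
    # accumulate in tenths so equal scores are exactly equal
    tenths = 0
    n = len(primer)
    for i, (p, t) in enumerate(zip(primer, window)):
        if t == "N" or t in _EXPAND[p]:
            continue
        if i == n - 1:
            tenths += 30
        elif i >= n - 5:
            tenths += 10
        else:
            tenths += 4
    return tenths / 10.0


def naive_best(primer, text, strand):
    query = primer
    if strand == "minus":
        query = "".join(_COMP[c] for c in reversed(primer))
    best = None
    for o in range(len(text) - len(primer) + 1):
        s = naive_score(primer, text[o:o + len(primer)]) if strand == "plus" else \
            naive_score(primer,
                        "".join(_COMP[c] for c in reversed(text[o:o + len(primer)])))
        if best is None or s < best[1]:
            best = (o, s)
    return best


class TestScoreSite:
    def test_perfect_match(self):
        assert score_site("ACGTACGTAC", "ACGTACGTAC") == (0, 0, False, 0.0)

    def test_non3_mismatch(self):
        n_non3, n_3, last, score = score_site("ACGTACGTAC", "ACGAACGTAC")
        assert (n_non3, n_3, last) == (1, 0, False)
        assert score == pytest.approx(0.4)

    def test_terminal_mismatch(self):
        n_non3, n_3, last, score = score_site("ACGTACGTAC", "ACGTACGTAT")
        assert last and score == pytest.approx(3.0)

    def test_three_prime_region_is_4_bases_before_terminal(self):
        # positions 5..8 of a 10-mer are the 1.0-weighted region
        primer = "ACGTACGTAC"
        for pos, weight in [(4, 0.4), (5, 1.0), (8, 1.0), (9, 3.0)]:
            window = list(primer)
            window[pos] = {"A": "C"}.get(window[pos], "A")
            _, _, _, score = score_site(primer, "".join(window))
            assert score == pytest.approx(weight), pos

    def test_degenerate_primer_base_matches_its_set(self):
        assert score_site("R", "A")[3] == 0.0
        assert score_site("R", "G")[3] == 0.0
        assert score_site("R", "C")[3] == pytest.approx(3.0)

    def test_target_n_matches_anything(self):
        assert score_site("ACGT", "NNNN")[3] == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            score_site("ACGT", "ACG")


class TestFindBestSite:
    def test_planted_exact_site(self, fwd30):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 100) + fwd30.sequence + random_dna(rng, 80)
        site = find_best_site(fwd30, make_contig(seq), "plus")
        assert (site.start, site.end, site.score) == (100, 120, 0.0)

    def test_prefers_lower_score(self, fwd30):
        p = fwd30.sequence
        near = "T" + p[1:]          # one non-3' mismatch: 0.4
        far = "TTT" + p[3:]         # three non-3' mismatches: 1.2
        seq = "G" * 30 + far + "G" * 30 + near + "G" * 30
        site = find_best_site(fwd30, make_contig(seq), "plus")
        assert site.start == 30 + len(p) + 30
        assert site.score == pytest.approx(0.4)

    def test_primer_longer_than_contig(self, fwd30):
        assert find_best_site(fwd30, make_contig("ACGTACGTAC"), "plus") is None

    def test_tie_breaks_to_smallest_start(self, fwd30):
        p = fwd30.sequence
        seq = "G" * 10 + p + "G" * 10 + p + "G" * 10
        site = find_best_site(fwd30, make_contig(seq), "plus")
        assert site.start == 10

    def test_minus_strand_finds_revcomp_site(self, rev217):
        rng = np.random.default_rng(1)
        planted = revcomp(rev217.sequence)
        seq = random_dna(rng, 60) + planted + random_dna(rng, 40)
        site = find_best_site(rev217, make_contig(seq), "minus")
        assert (site.start, site.end, site.strand) == (60, 80, "minus")
        assert site.score == 0.0

    @pytest.mark.parametrize("strand", ["plus", "minus"])
    def test_agrees_with_naive_oracle(self, strand, fwd30):
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = random_dna(rng, int(rng.integers(25, 400)))
            site = find_best_site(fwd30, make_contig(seq), strand)
            o_start, o_score = naive_best(fwd30.sequence, seq, strand)
            assert site.start == o_start
            assert site.score == pytest.approx(o_score)

    def test_strand_consistency(self, fwd30):
        """Minus-strand scoring equals plus-strand scoring on the
        reverse-complemented contig: best scores agree, and each winner's
        mirrored coordinate scores identically in the other orientation
        (the smallest-start tie-break is per-orientation, so the winning
        offsets themselves may mirror to different ties)."""
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 200)
        n = len(fwd30.sequence)
        minus = find_best_site(fwd30, make_contig(seq), "minus")
        plus_on_rc = find_best_site(fwd30, make_contig(revcomp(seq)), "plus")
        assert minus.score == plus_on_rc.score
        mirrored = len(seq) - plus_on_rc.end
        window = seq[mirrored:mirrored + n]
        assert score_site(fwd30.sequence, revcomp(window))[3] == minus.score


class TestPredictAmplicon:
    def _contig_with_sites(self, fwd, rev, gap=320, lead=100, tail=60, seed=0):
        rng = np.random.default_rng(seed)
        seq = (random_dna(rng, lead) + fwd.sequence + random_dna(rng, gap)
               + revcomp(rev.sequence) + random_dna(rng, tail))
        return make_contig(seq, join_pos=lead + len(fwd.sequence) + gap // 2)

    def test_planted_pair_coordinates(self, fwd30, rev217):
        c = self._contig_with_sites(fwd30, rev217)
        amp = predict_amplicon(fwd30, rev217, c)
        assert (amp.start, amp.end) == (100, 100 + 20 + 320 + 20)
        assert amp.length == 360
        assert amp.fwd_site.score == 0.0 and amp.rev_site.score == 0.0

    def test_reverse_only_upstream_gives_none(self, fwd30, rev217):
        rng = np.random.default_rng(2)
        seq = (random_dna(rng, 50) + revcomp(rev217.sequence)
               + random_dna(rng, 100) + fwd30.sequence + random_dna(rng, 30))
        # best reverse site precedes the forward site; no downstream offset
        # scores anywhere near it, but an amplicon is only reported when the
        # reverse placement lies at/after the forward site's end
        amp = predict_amplicon(fwd30, rev217, make_contig(seq))
        if amp is not None:
            assert amp.rev_site.start >= amp.fwd_site.end
            assert amp.rev_site.score > 1.0

    def test_high_score_sites_still_reported(self, fwd30, rev217):
        rng = np.random.default_rng(4)
        amp = predict_amplicon(fwd30, rev217, make_contig(random_dna(rng, 300)))
        # random background: sites exist but score badly; hit/miss is the
        # coverage layer's decision
        assert amp is None or (amp.fwd_site.score > 1.0 or amp.rev_site.score > 1.0)


@pytest.fixture(scope="module")
def mixed_fixture(fwd30, rev217):
    """10 matched records: 8 perfect plants, 2 with 3 forward mismatches
    (score 1.2, missing at threshold 1.0)."""
    spec = coverage_spec(n_records=10, target_coverage=0.8, n_phyla=2, seed=21)
    fx = make_fixture(spec, fwd30, rev217)
    contigs, _ = build_sis(fx.unite_records, fx.silva_records)
    return fx, contigs


class TestEvaluateCoverage:
    def test_overall_coverage(self, mixed_fixture, fwd30, rev217):
        _, contigs = mixed_fixture
        report = evaluate_coverage(fwd30, rev217, contigs)
        assert report.overall.n_records == 10
        assert report.overall.n_hits == 8
        assert report.overall.coverage == pytest.approx(0.8)

    def test_threshold_infinity_covers_all(self, mixed_fixture, fwd30, rev217):
        _, contigs = mixed_fixture
        report = evaluate_coverage(fwd30, rev217, contigs,
                                   score_threshold=float("inf"))
        assert report.overall.coverage == 1.0

    def test_per_group_counts_match_manifest(self, mixed_fixture, fwd30, rev217):
        fx, contigs = mixed_fixture
        report = evaluate_coverage(fwd30, rev217, contigs)
        for phylum, (n_rec, n_hit) in fx.manifest.per_phylum.items():
            grp = report.per_group[phylum]
            assert (grp.n_records, grp.n_hits) == (n_rec, n_hit)

    def test_group_sums_equal_overall(self, mixed_fixture, fwd30, rev217):
        fx, contigs = mixed_fixture
        report = evaluate_coverage(fwd30, rev217, contigs)
        rank_groups = [g for g in report.per_group if g in fx.manifest.per_phylum]
        assert sum(report.per_group[g].n_records for g in rank_groups) == 10
        assert sum(report.per_group[g].n_hits for g in rank_groups) == 8

    def test_threshold_monotonicity(self, mixed_fixture, fwd30, rev217):
        _, contigs = mixed_fixture
        covs = [
            evaluate_coverage(fwd30, rev217, contigs,
                              score_threshold=t).overall.coverage
            for t in (0.0, 0.4, 1.0, 1.2, 3.0, float("inf"))
        ]
        assert covs == sorted(covs)

    def test_unknown_grouping_rank(self, mixed_fixture, fwd30, rev217):
        _, contigs = mixed_fixture
        with pytest.raises(ValueError):
            evaluate_coverage(fwd30, rev217, contigs, grouping_rank="clade")

    def test_empty_contigs_raises(self, fwd30, rev217):
        with pytest.raises(ValueError):
            evaluate_coverage(fwd30, rev217, [])


class TestAmpliconStats:
    @pytest.fixture(scope="class")
    def staggered(self, fwd30, rev217):
        spec = FixtureSpec(
            n_phyla=1, n_species=3, n_unite_records=3,
            silva_match_plan=("species",) * 3,
            plant_plan=tuple(PlantPlan(amplicon_length=a) for a in (350, 360, 370)),
            seed=9,
        )
        fx = make_fixture(spec, fwd30, rev217)
        contigs, _ = build_sis(fx.unite_records, fx.silva_records)
        return contigs

    def test_mean_sd_hand_values(self, staggered, fwd30, rev217):
        mean, sd, n = amplicon_stats(fwd30, rev217, staggered)
        assert (mean, n) == (360.0, 3)
        assert sd == pytest.approx(10.0)

    def test_single_hit_sd_none(self, staggered, fwd30, rev217):
        mean, sd, n = amplicon_stats(fwd30, rev217, staggered[:1])
        assert n == 1 and sd is None and mean == 350.0

    def test_no_hits(self, staggered, fwd30, rev217):
        mean, sd, n = amplicon_stats(fwd30, rev217, staggered,
                                     score_threshold=-1.0)
        assert (mean, sd, n) == (None, None, 0)
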