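# Methods

## Problem setting

Fungal community profiling amplifies the ITS1 spacer between the 18S and
5.8S rRNA genes. Assessing a primer pair's taxonomic reach *in silico*
needs reference sequences spanning both primer targets, but the public
collections split the locus: 18S references carry semicolon-delimited
lineages of variable depth, while ITS references use a fixed seven-rank
`k__;p__;c__;o__;f__;g__;s__` convention. This package harmonizes the two,
synthesizes joint 18S-ITS1-5.8S ("SIS") contigs, and evaluates primer
pairs against them.

## Taxonomy matching

Names are normalized (rank prefix stripped, underscores to spaces,
lowercased, whitespace collapsed) before comparison; normalization is
idempotent. An ITS lineage is matched against the 18S collection rank by
rank from species up to kingdom; the first rank whose normalized name
occurs — as a whole name, never a substring — anywhere in an 18S lineage
wins. Whole-name equality avoids false merges such as *Candida* inside
"Candidatus". Placeholder names (empty, `unidentified…`, open nomenclature
`… sp`) are skipped: they label missing identification, not taxa. Several
choices here were genuinely open and are pinned as follows:

* **Ties** among 18S records at the winning rank go to the
  lexicographically smallest record id — deterministic and independent of
  input order.
* **No fuzzy matching**: synonym/anamorph resolution and edit-distance
  matching are out of scope; equality after normalization is the whole
  criterion.

## SIS contig construction

Each matched ITS record is concatenated onto its full 18S reference
(`sequence = 18S + ITS`, `join_pos = |18S|`). The full 18S is retained,
not just the 3′ design window, so a forward candidate that also binds a
conserved upstream 18S site is caught during scanning. No junction
trimming is applied by default — straight concatenation is the reference
behaviour — but `trim_overlap=k` removes an exact duplication (ITS prefix
equal to the 18S suffix, length ≥ k) for ITS records that retain trailing
18S bases. Contigs keep provenance in the header
(`>{its_id}|{18S_id}|{match_rank} {lineage}`) with a TSV sidecar carrying
join positions. Species counts use the fixed-rank ITS-side lineage only,
excluding placeholders; identical contigs are not deduplicated (several
records per species is the normal case).

## Melting temperatures

Three composition-only formulas are pinned, with `method` explicit at
every call site (°C; `N` = length, `GC` = G+C count):

| method | formula | intended range |
|---|---|---|
| `wallace` | 2·(A+T) + 4·(G+C) | < 14-mers (warns beyond) |
| `basic` | 64.9 + 41·(GC − 16.4)/N | ≥ 14-mers |
| `salt_adjusted` | 100.5 + 41·GC/N − 820/N + 16.6·log₁₀[Na⁺] | Na⁺ default 0.05 M |

Degenerate IUPAC positions contribute the average of their expansion set
(R counts 0.5 toward GC), giving one deterministic number per degenerate
oligo. The pairing screen compares |ΔTm| under a single method against a
caller-supplied threshold (conventionally 5 °C); the default reporting
method is `basic`. Note the bundled primer pair ITS1-48F/ITS1-217R sits at
6.15 °C under `basic`, so the threshold is a parameter, never an assertion
about the bundled set.

## Degenerate candidate design

From a gapped alignment (consumed pre-aligned; alignment itself is out of
scope), a `primer_len` window slides over all columns. Windows containing
any column with gap fraction ≥ 0.5 are rejected. Per column, every base
with frequency ≥ `min_freq` (default 0.10) among non-gap characters joins
the consensus set, encoded as the unique IUPAC code; if nothing reaches
the threshold the single most frequent base is kept (ties alphabetical).
Row ambiguity codes are expanded fractionally before thresholding.
Candidates are dropped when degeneracy (product of per-position set sizes)
exceeds `max_degeneracy` (default 8) or sensitivity falls below
`min_sensitivity` (default 0.60); sensitivity counts a row as matched only
when it is gap-free in the window and every base lies in the consensus set
— a primer cannot anneal across a deletion at its binding site. Ranking is
the total order (sensitivity desc, degeneracy asc, start column asc).
Useful consequences, verified as properties: raising `min_freq` never
increases degeneracy, and with `min_freq = 0` and unbounded degeneracy the
sensitivity equals exactly the gap-free row fraction.

## In-silico PCR

Binding is modelled gaplessly: every offset of every contig is scored, a
position matching when the contig base belongs to the primer base's IUPAC
expansion set (`N` in the reference matches anything — database ambiguity
should not penalize a primer). Mismatches are partitioned into the
terminal 3′ base (weight 3.0), the four bases preceding it (1.0), and the
remainder (0.4); these are the standard published defaults of in-silico
primer scoring, exposed as configuration. Scores are computed in exact
tenths (integer arithmetic) so equal scores tie exactly and the
smallest-start tie-break is well defined. Reverse primers are scanned as
their reverse complement against the plus strand with the position weights
mirrored, since their 3′ terminus maps to the window's left edge.

An amplicon runs from the forward site's 5′ start to the downstream
reverse site's end (both footprints included, matching sequencer-facing
length conventions). A contig is a *hit* when both best sites score ≤ the
threshold (default 1.0) in productive orientation and the amplicon is
≤ 700 bp (short-read platform cap). Coverage is reported per grouping rank
(default phylum) with optional named extra rows (default: genus
*Candida*); extra rows overlap the rank partition and are excluded from
overall sums. Because record-level and species-level coverage can differ,
both are reported (species-level as a secondary overall figure,
placeholders excluded). Amplicon statistics use the sample standard
deviation (n−1); SD is undefined at a single hit and reported as missing.

Pair screening retains forward×reverse combinations with |ΔTm| below the
threshold and mean predicted amplicon length (over amplicons ≤ the hard
cap) inside 300–500 bp — i.e. a 400 ± 100 bp target — sorted by coverage.

## Synthetic data generator

`mycoprimer.fixtures` emulates the two input dialects at desk scale. Study
conditions (defaults): 18S lengths 1600–1800 bp (full-gene scale), ITS
record lengths 400–700 bp (typical ITS1+5.8S span), nine phyla (the
panel size a coverage heat map reports on), planted amplicons of 400 bp
(the screening target), and a per-record plan controlling (a) the rank at
which the taxonomy matches, and (b) planted forward/reverse sites with
exact mismatch counts (non-3′ filled first, then 3′, terminal last, at
deterministic positions).

Design points:

* The forward site is planted as the final bases of the 18S record — inside
  the 250-bp 3′ design window — so the amplicon length is controlled
  entirely by the reverse-site offset in the ITS record and is independent
  of the 18S length. This keeps planted truth exact even when two records
  of the same species tie to the same 18S reference.
* The match plan is validated in closed form before any sequence is drawn:
  name-exposure sets per rank detect plans whose name sharing would force
  a deeper match than requested, and mismatch/geometry infeasibilities
  (amplicon shorter than the primer footprints, mismatch counts beyond
  primer capacity, ITS range too short) raise before output.
* Background is uniform over {A,C,G,T} from a single seeded PCG64 stream
  (pinned generator, platform-independent; identical seed ⇒ byte-identical
  files). A rejection step redraws any background segment in which a
  non-planted offset would score at or below max(threshold, planted
  score), and a final whole-contig check covers windows straddling the
  18S/ITS junction — so the planted truth is the unique truth and tests
  cannot flake.

What the generator does **not** emulate: phylogenetic correlation between
sequences (backgrounds are i.i.d., so cross-binding between unrelated
records is absent by construction), length/composition biases of real
rRNA, chimeras, and sequencing error. Passing tests therefore certify the
algorithmic contracts — scanning, scoring, matching, counting — not the
coverage a primer would achieve on a real reference release, which depends
on the release's actual diversity.

## Problem sizes and numerics

The shipped verification runs use 3–50 records per fixture and contigs of
roughly 2 kb, sizes at which the exhaustive scan is exact and fast; the
vectorized scanner is O(contig × primer) per contig with no heuristics, so
results at larger scale differ only in wall time. All randomness is
seeded; reports and databases are written in sorted order so rebuilds are
byte-identical. Degenerate inputs: empty collections raise structured
errors where the contract requires an object, and return empty/zero
results where a count is the natural answer (summaries of zero contigs,
pair enumeration over empty primer lists).

## Known limitations

* Gapless binding model: primer-length indels at a binding site are not
  modelled (they are rare and would need affine-gap scanning).
* No thermodynamic nearest-neighbour model, hairpin/dimer screening, or
  PCR efficiency simulation; Tm is composition-only by design.
* Taxonomy matching is lexical. Anamorph/teleomorph synonymy and
  misspellings in real releases reduce match rates and are out of scope.
* The bundled catalog covers the nine primers used in the examples, not
  the full historical literature.
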