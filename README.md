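# mycoprimer

Engineering and evaluation of fungal **ITS1** amplicon primers.

Mycobiome (fungal microbiome) surveys amplify the ITS1 region — the
variable spacer between the 18S and 5.8S rRNA genes — and sequence it on
short-read platforms. Commonly used "universal" ITS1 primers were designed
from small historical collections of soil fungi and miss much of the known
fungal diversity. Evaluating a candidate primer pair *in silico* requires a
reference that spans both primer targets (forward in the 3′ end of 18S,
reverse in 5.8S), but public databases hold the two regions separately:
18S collections carry variable-depth lineages, ITS collections carry fixed
seven-rank lineages, and no database provides the intact 18S-ITS1-5.8S
contig.

`mycoprimer` closes that gap with four connected stages:

1. **Taxonomy harmonization** — parse both lineage header dialects,
   normalize names, and match every ITS record to an 18S reference at the
   lowest (most specific) shared taxonomic rank.
2. **SIS database construction** — concatenate each matched 18S sequence
   with its ITS record into a simulated **S**SU-**I**TS1-5.8**S** contig,
   keeping full provenance (source ids, match rank, join position).
3. **Degenerate primer design** — slide fixed-length windows over a gapped
   alignment, build IUPAC consensus sequences (include every base at
   frequency ≥ `min_freq` per column), and rank candidates by sensitivity
   (fraction of rows matched exactly) and degeneracy.
4. **In-silico PCR** — exhaustively scan each primer over every contig with
   3′-weighted mismatch penalties, predict amplicons, and report taxonomic
   coverage per phylum (plus *Candida* as a named extra group) and overall.

## The scoring model

A gapless placement of a primer of length *L* on a contig is scored

```
score = 0.4 · m_body + 1.0 · m_3' + 3.0 · [terminal mismatch]
```

where `m_3'` counts mismatches in the four bases preceding the 3′ terminus
and `m_body` the rest; a mismatched terminal base blocks polymerase
extension and costs 3.0. A contig counts as *covered* by a pair when the
best forward (plus strand) and reverse (minus strand, downstream) sites
both score ≤ 1.0 and the implied amplicon is ≤ 700 bp. Pairs are screened
on |ΔTm| (composition-only melting temperatures: Wallace rule, the basic
`64.9 + 41·(GC − 16.4)/N` formula, or its salt-adjusted variant; degenerate
positions count fractionally) and on mean predicted amplicon length
(default window 400 ± 100 bp).

Because the real reference databases are large external downloads, the
package ships a first-class synthetic-data generator (`mycoprimer.fixtures`)
that emulates both FASTA dialects with planted binding sites of known
mismatch structure, controlled taxonomy overlap, and a ground-truth
manifest — the entire pipeline is testable offline and every expected
number is known by construction.

## Worked example

```
$ mycoprimer simulate --n-records 20 --coverage 0.8 --seed 7 --out fix
silva   20
unite   20
manifest        fix/manifest.json

$ mycoprimer build-sis --unite fix/unite.fasta --silva fix/silva.fasta --out sis.fasta
contigs 20
species 20
matched 20/20

$ printf 'ITS1-30F\tforward\tGTCCCTGCCCTTTGTACACA\nITS1-48F\tforward\tACACACCGCCCGTCGCTACT\n' > f.tsv
$ printf 'ITS1-217R\treverse\tTTTCGCTGCGTTCTTCATCG\n' > r.tsv

$ mycoprimer tm --method basic f.tsv
name    length  gc      tm
ITS1-30F        20      0.5500  53.83
ITS1-48F        20      0.6500  57.93

$ mycoprimer pairs --forwards f.tsv --reverses r.tsv --sis sis.fasta --out pairs.tsv
pairs   1
$ cat pairs.tsv
fwd     rev     tm_diff mean_amplicon   sd_amplicon     coverage        n
ITS1-30F        ITS1-217R       2.05    400.00  0.00    0.8000  16
```

Reading the output: the 20 simulated ITS records all matched an 18S
reference (20 contigs, 20 species). ITS1-30F melts at 53.83 °C and
ITS1-217R at 51.78 °C under the basic formula, so the pair passes the
ΔTm < 5 °C screen at 2.05 °C, while ITS1-48F (57.93 °C, ΔTm 6.15 °C) is
rejected — only one pair survives. The surviving pair amplifies 16 of the
20 contigs (coverage 0.80, the value planted by the simulator) with a mean
predicted amplicon of 400 bp, inside the 300–500 bp screening window.
`mycoprimer evaluate` additionally writes per-phylum coverage tables, the
amplicon list, and a group × pair coverage matrix suitable for heat-map
plotting. All coordinates in outputs are 0-based half-open.

The bundled primer catalog (`mycoprimer.catalog`) carries the four widely
used published ITS1-region primers and five custom-designed ones used in
the examples above.

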