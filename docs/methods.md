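# Methods

`splicevar` implements a desk-scale version of the splice-junction route to
novel transcription-factor isoforms: candidate junctions are screened,
interpreted as alternative-splicing events against a reference transcript,
edited into novel isoform models, and translated into predicted protein
consequences. This note documents the models, the operational choices behind
every tunable parameter, and what the synthetic fixtures do and do not show.

## Coordinate model

All coordinates are 0-based half-open (BED convention); GTF's 1-based
inclusive coordinates are converted at the I/O boundary. Genomic intervals
never flip with strand; all transcript-level offsets and sequences are on the
sense strand. One deliberate deviation from the Ensembl GTF dialect: CDS
bounds *include* the terminal stop codon, so an n-aa protein has a spliced
CDS of 3(n+1) nt. A CDS that fails its structural or sequence checks at load
(length not a multiple of 3, missing ATG/stop) flags the transcript with a
warning rather than rejecting it — real annotations contain such records, and
junction screening needs only the intron coordinates.

## Junction screening

A junction is the genomic interval of its excised intron plus per-sample read
counts. Four filters run in a fixed order — read count, repeat overlap,
novelty, EST/prediction support — so each rejected junction carries exactly
one reason, the first failure.

* **Read count** (default: ≥ 2 reads in ≥ 1 sample). The two knobs
  `min_reads_per_sample` and `min_samples_passing` cover both published
  phrasings of the threshold ("two reads … in at least one dataset" vs "two
  reads/sample"); the at-least-one-dataset reading is the default because it
  is the operational description of the original screen.
* **Repeat overlap**, default policy `either_site`: a junction fails when a
  repeat touches either terminal (splice-site) dinucleotide of the intron.
  Rationale: spurious junctions from mis-mapped reads concentrate at splice
  sites that cross repeats. `any_overlap` (whole intron) is available for a
  stricter screen; which of the two the original analysis used is not
  determinable, so both are exposed.
* **Novelty** is exact-coordinate matching against every annotated intron
  (junction evidence is base-resolved; fuzzy matching would blur alternative
  donors/acceptors into annotated introns).
* **Support** is exact matching against a track of spliced-EST or
  gene-prediction introns, and can be disabled.

Candidate count is monotone non-increasing in the read threshold and the
screen partitions its input; both are property-tested.

## Event classification and reconstruction

A template transcript is chosen per junction: most shared splice sites, ties
broken by longest CDS, then lexicographic id (deterministic, favours coding
context). Geometry against the template's exon chain yields seven categories:
`CASSETTE_SKIP`, `MULTI_EXON_SKIP`, `ALT_DONOR`, `ALT_ACCEPTOR`,
`ALT_DONOR_PLUS_SKIP` (a donor inside an exon that also bypasses whole
exons), `EXON_GAIN` and `EXON_GAIN_CRYPTIC_ACCEPTOR`. Exon gain requires a
junction *pair* bracketing an unannotated interval inside one annotated
intron; when several acceptor-side junctions pair with one donor-side
junction, the acceptor nearest the annotated donor defines the full gained
exon and the others are cryptic-acceptor events. An unpaired intron-internal
acceptor is reported as `ALT_ACCEPTOR`. Intron retention and alternative
polyadenylation are out of scope.

Reconstruction is template editing: skipped exons removed, trimmed bounds
applied, gained exons inserted, the spliced sequence recomputed from the
genome, and every novel intron graded canonical (GT..AG), minor (GC-AG,
AT-AC) or noncanonical on the transcript strand. Exon numbers in reports are
1-based in transcript order.

## ORF selection and consequence

`scan_orfs` reports every AUG-initiated ORF ending at the first in-frame stop
codon; open-ended ORFs are not reported, and ORFs under `min_protein_aa`
(default 30 aa) are suppressed as translationally implausible noise. Kozak
context is reduced to the two dominant determinants: purine at −3 **and** G
at +4 → strong; exactly one → adequate; neither → weak (positions outside the
sequence never match). Start selection defaults to `five_prime_first`: the
5'-most AUG in at least adequate context, falling back to the 5'-most AUG;
this single policy reproduces both a downstream-AUG truncation (start exon
skipped) and an upstream-AUG extension (stop-free upstream AUG created), with
`longest_orf` available for sensitivity analysis.

Consequence classification aligns the novel ORF to the canonical one by
genomic codon-position triples: identical codon lists → `UNCHANGED`; the
canonical list as a strict suffix → `N_TERMINAL_EXTENSION`; the novel list a
strict suffix of the canonical → `N_TERMINAL_TRUNCATION`; identical first and
last codons with only internal codons missing → `IN_FRAME_INTERNAL_DELETION`
(possible only when the removed coding length is a multiple of 3); anything
else → `FRAMESHIFT_PTC`, with the lost C-terminal residue count measured from
the last shared codon. Domain loss is table-driven: a domain overlapping the
lost canonical residue range by any amount is reported lost, with its overlap
fraction.

NMD candidacy uses the classic 50-nt rule with a strict inequality: a PTC is
a candidate when the 3' end of the stop codon lies more than `rule_nt`
(default 50) nt upstream of the last exon–exon junction; single-exon isoforms
are never candidates. The boundary convention (measuring from the stop
codon's 3' end, strict `>`) is an operational choice — published statements
of the rule vary by a few nt — and `rule_nt` is configurable.

The C2H2 zinc-finger scanner implements PROSITE PS00028,
`C-x(2,4)-C-x(3)-[LIVMFYWC]-x(8)-H-x(3,5)-H`, as a leftmost, non-overlapping
scan with shortest admissible spacer expansion (deterministic counts); an
overlapping mode exists behind a flag. KRAB domains are handled only through
the domain table, not by profile search.

## Validation toolkit

Amplicon prediction is exact-match in-silico RT-PCR: the forward primer on
the spliced sense sequence, the reverse primer as its reverse complement
downstream, product size the span from the forward primer's 5' end through
the projection of the reverse primer's 5' end. This convention makes product
sizes additive in inserted/deleted sequence between the primer sites (the
46 → 205/149 arithmetic). Multiple site combinations are all reported and
flagged; the shortest is the headline product (dominant band under standard
PCR kinetics). Mismatch tolerance and ambiguity codes are out of scope.

Diversity profiling of a protein alignment reports, per column, Shannon
entropy of residue frequencies normalised by ln 20 (identical column → 0), or
`one_minus_consensus`. Gaps are excluded from frequencies; an all-gap column
scores 0 and is flagged. The metric used in the original conservation figure
is unnamed, so neither option is claimed identical to it.

## Synthetic scenarios

The generator emits, per scenario, a FASTA genome, GTF annotation, BED repeat
and EST-support tracks, a junction table, primer and domain TSVs, and a flat
key-value truth file sufficient to score every downstream stage. Scenario
parameters are the published structural numbers: a 763-codon ORF losing its
start exon with the next in-frame AUG 216 nt downstream (→ 691 aa); a 159-nt
exon gained into intron 3 with a cryptic acceptor retaining 103 nt, primers
giving a 46-nt annotated product (→ 205/149 nt); in-frame losses of residues
12–36 (of 580) and 168–244 (of 1188); a 418-nt two-exon skip (frameshift +
PTC + NMD); one in-frame and one PTC-forming multi-exon skip of a 325-codon
ORF; and an event creating a strong-context AUG 201 nt upstream of a
549-codon ORF (→ 616 aa). Where an annotated length is not printed (the
exon-gain gene's 581 codons, the 580- and 325-codon ORFs), it is a scenario
parameter chosen near the real protein's size and only the differences are
meaningful.

Engineering guarantees replace chance: random exonic stretches are drawn so
that `ATG` cannot occur (coding codons come from a 41-codon set that can form
neither ATG nor a stop across codon boundaries), every annotated and
engineered intron is GT..AG, decoy ORFs terminate within fewer than 30
codons, and read counts are fixed integers. Genes are built in plus
orientation and mirrored for minus-strand output, which leaves all
transcript-level truth identical by construction. The fixtures therefore test
the *logic* of every rule under clean conditions; they do not emulate read
noise, soft-clipped alignments, overlapping genes, paralogy, non-canonical
splice sites in real annotations, or expression-level effects, so passing
them says nothing about mapping artefacts upstream of the junction table.

The frameshift presets compute their expected protein length with the
generator's own independent codon walk over the edited coding stream (an
engineered shifted-frame stop bounds the walk; an earlier chance stop, if
one arises, is what both the walk and the pipeline must find).

## Expression summary

Gene-level normalisation is RPKM with tier cut-offs low < 1 ≤ medium ≤ 30 <
high. The original normalisation scheme and cut-offs are unspecified; these
defaults are labelled non-authoritative and configurable.

## Determinism and problem sizes

Every generator is driven by `random.Random` seeded from (scenario, seed), so
identical inputs give byte-identical files, and the pipeline report is
byte-identical across reruns of the same configuration. The test suite runs
the full preset grid (9 variant scenarios × 2 strands × 10 seeds) plus
property suites of 100–200 random instances per oracle; toy genomes are a few
kilobases, which keeps the whole suite in the seconds range while exercising
ORFs up to 4.4 kb.

## Known limitations

* Reconstruction is template editing, not assembly: an isoform whose
  structure deviates from the template beyond the evidenced junctions cannot
  be represented.
* Exon-gain classification needs both flanking junctions; a gained exon
  evidenced on one side only degrades to `ALT_ACCEPTOR`/`ALT_DONOR`.
* The seven-category taxonomy was reconstructed from the realised geometries
  plus standard AS vocabulary; the original upstream classification scheme is
  not published in a recomputable form, so category *names* may not map
  one-to-one.
* Protein consequences are sequence-level predictions only; no structure,
  surface accessibility or translation-efficiency modelling.
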