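# Methods

## Problem and definitions

Two genes are given, one per species, assumed one-to-one orthologs, each
with a set of coding transcripts (ordered CDS exons, CCDS-style: the coding
region runs from the start codon through the stop codon inclusive). Across
species, *orthologous exon isoforms* are orthologous exons with conserved
exon–intron borders; *splicing orthologs* are transcripts whose exons are
orthologous exon isoforms in the same order, coding for similar proteins.
The package labels every transcript of a *known* species with respect to a
*target* species: paired with a splicing ortholog, predicted but not yet
annotated (*yet-to-be-found*), or species-specific. Two independent
procedures — a nucleotide-level predictor and a protein-level controller —
must agree before a label is considered confirmed; disagreements are
reported as unresolved rather than silently resolved.

## The common block reference

All exon starts/ends of each species' transcripts (including start/stop
codon positions) partition that species' exonic regions into atomic
segments. Each segment, extended by 20 nt of flanking genomic context on
each side, is located in the other gene by local alignment (match +1,
mismatch −1, gap −2). A segment is *matched* when its best hit is
unambiguous (no co-optimal hit at a disjoint location), reaches 70 %
identity over the aligned segment-plus-flanks, and covers ≥ 90 % of the
segment core; it is a *best reciprocal hit* when realigning the hit (with
flanks) in the original gene recovers the segment. Deterministic local
alignment replaces the similarity-search step of the original protocol so
that results are reproducible without an external search tool; both the
flank length and the identity threshold are exposed in the run
configuration.

Gene pairs are screened before block construction: two distinct segments of
one species hitting overlapping spans of the other indicate duplicated
exons; confidently matched segments whose hit order crosses indicate
rearrangement. Either condition rejects the pair (rejection is a reported
value with a reason, mirroring the screening of gene pairs with homology
problems). The duplication test deliberately considers all confident hits,
not only reciprocal ones: near-identical duplicate copies tie the best hit
and would otherwise evade the reciprocity-based test entirely.

Matched segment boundaries are projected through the alignment coordinate
maps into the other species (projected boundaries within 2 nt of an
existing boundary snap onto it, absorbing alignment slop); the refined
partitions of the two genes are then paired span-by-span into *blocks*.
A block carries a span in a species only when that species' transcripts use
it, so a cassette exon present in only one annotation set yields a
one-sided block. Blocks are labelled A, B, … (then AA, AB, …) in gene order
of the first species, one-sided blocks of the second species interleaved at
their mapped position. Construction guarantees the containment invariant —
every block span is wholly inside or wholly outside every transcript's exon
set — because each partition refines its own species' exon boundaries; a
violation after projection rejects the pair (`inconsistent_borders`).
Blocks separated by boundaries that no transcript uses are not merged.

The *gene model* of a species is the ordered string of its blocks decorated
with signals: `[` before a block at whose 5′ boundary a start codon lies in
at least one transcript, `]` after a stop, `<` after a block whose 3′
boundary is a donor site, `>` before a block whose 5′ boundary is an
acceptor site. Symbols attached to one block always appear in the fixed
order `[ > label < ]`, which makes every transcript string a subsequence of
its gene model by construction.

## The predictor

Scanning consults only the known species' gene model and the raw target
gene sequence — no target annotations. Each model block (with flanks) is
located in the target gene under the same identity/coverage/ambiguity
rules; found blocks must be collinear (a longest-increasing-subsequence
filter drops hits that fall out of order, so spurious repeats cannot
populate the result). A donor or acceptor signal anchored on a found block
is found when the two intronic nucleotides at the border, projected through
the block's alignment (extrapolated gap-free where the local alignment
trimmed a diverged flank), are conserved in the target. The successes form
the substring S of the gene model.

A transcript is *executable* when every donor and every acceptor block of
its string is in S with its signal found — both the block and its signal
are required, since a border whose dinucleotide is not conserved is not a
working splice site. Single-exon transcripts have no donor or acceptor
block; they are reported as indeterminate and excluded from all counts
(the analysis concerns multi-exon transcripts).

Matching runs in *flexible mode*: two transcripts have the same splicing
pattern when their symbol strings agree from the donor block of the first
intron through the acceptor block of the last intron. The anchoring donor
and acceptor block labels are part of the compared interval — the internal
border of a terminal exon must itself be orthologous — while start and stop
positions within the terminal exons remain free. Because the shared anchor
block lies in both terminal exons, the overlap of terminal-exon blocks is
implied and pattern equality alone decides a match. Within one species,
transcripts with identical patterns are duplicates for this analysis: both
procedures keep the isoform with the smallest accession (numeric on the
CCDS integer, lexicographic fallback); pattern equality being transitive
makes this grouping well defined.

## The controller

Proteins are obtained by splicing and translating each deduplicated
transcript (standard code; the terminal stop is required and stripped).
A translation containing an internal stop codon is the signature of a
candidate frame-shift and is excluded before pairing. Each internal exon
junction is assigned a residue: a phase-0 junction takes the residue whose
codon ends at the junction, a phase-1/2 junction the residue whose codon
spans it. The convention is arbitrary — what matters is that it is applied
identically to both species.

Within groups of equal exon count, all isoform pairs are aligned by a
semi-global dynamic program: Blosum62 substitution scores, leading and
trailing gaps free on both sequences, internal gaps affine at open 11 /
extend 1 (a standard Blosum62 companion; the original description leaves
internal gap costs unstated, so they are configurable). Tie-breaking is
fixed — substitution preferred over a gap, a gap in the first sequence over
one in the second, and among equal-scoring end points the one consuming
most of both sequences — so alignments are bit-reproducible. Candidates are
*unique* best reciprocal hits: strict score maxima on both sides, any tie
disqualifying its member.

A candidate is accepted when (i) every corresponding junction pair shares
an alignment column; (ii) no gap character occurs within v = 2 columns of
any junction column (windows truncate at the alignment ends) — insertions
and deletions elsewhere within an exon are allowed; and (iii) the last ≤ 10
columns of the first exon (ending at the first junction column) and the
first ≤ 10 columns of the last exon score non-negatively under Blosum62,
gap columns scoring their gap penalty. The v and 10-residue windows count
alignment columns, not per-sequence residues. Terminal windows are clipped
to the region where both sequences have started/not yet ended, which
handles very small terminal exons by truncation (a warning is logged for
proteins shorter than the window). Rule (iii) exists because a first or
last junction position can be preserved even when the terminal exons are
unrelated.

## Co-validation, metrics, cohorts

Predictor classes are confronted with the controller list: found ∧
controlled (same partner) → splicing ortholog; yet-to-be-found ∧
uncontrolled → confirmed yet-to-be-found; non-executable ∧ uncontrolled →
confirmed species-specific. Every other combination is unresolved, with
subtype `found_not_controlled` (including a pair whose partner differs
between the procedures), `ytbf_but_controlled` or `specific_but_controlled`.
The four classes partition the analyzed set, so a + b + c + unresolved = d
on every run.

Precision is a/(a+b) — splicing orthologs over positive predictions
(orthologs plus confirmed yet-to-be-found); unresolved cases enter neither
numerator nor denominator. Recall is the number of splicing orthologs over
the number of known target-species transcripts. Metrics are reported
rounded to two decimals with the exact value retained in the CSV output.
Transcripts carrying release timestamps can be partitioned into cohorts by
release boundaries (default 2, 7, 19; a missing release goes to a designated
unknown cohort excluded from per-cohort statistics), and cumulative
ortholog counts over a release sequence use the later release of a pair's
two members, yielding non-decreasing curves.

## The synthetic generator

The generator builds an ancestral multi-exon gene — by default 6–8 exons of
30–90 nt, introns of 40–80 nt with canonical GT/AG dinucleotides, ATG
start, stop codon included — and derives the two species by independent
point substitution. `divergence` is the expected pairwise divergence
between the two genes (default 0.05); each lineage receives half. Exon
lengths are multiples of 3, so every junction has phase 0 and every
alternative event preserves reading frame across isoforms; nonzero junction
phases are exercised by unit tests instead. Start/stop codons, splice
dinucleotides and the motifs of planned alternative sites are protected
from substitution — the realistic footprint of purifying selection, and the
reason generated truth labels stay well defined — and coding substitutions
that would create a stop are resampled. Optional intronic indels
(geometric lengths, capped at 5 nt) spare splice borders; coding indels are
not modelled, matching the curated character of CCDS annotations.

Events draw distinct internal exons: exon skipping, donor shifts of 3/6 nt,
acceptor shifts (including the NAGNAG 3-nt tandem acceptor, installed as a
`…AG|CAG…` motif), a species-specific cassette exon (physically deleted
from the other gene — the analogue of a one-sided block), an internal-ATG
start shift, and a read-through stop shift into the intron. Each event
isoform is present in both species, or in one, at random; presence yields
the ground truth directly: both → ortholog, one side without the cassette
exon → yet-to-be-found, cassette isoform → species-specific.

What the generator does not emulate: paralogy and gene families, repeat
content, non-canonical splice sites, coding indels and real frame-shifts,
UTRs, and realistic codon/indel evolutionary models. Passing the end-to-end
tests therefore demonstrates correctness of the procedure under clean
one-to-one orthology with point divergence, not performance on repeat-rich
or paralog-confounded real genomes — on real data the screening stage is
expected to discard such pairs, as the rejected-gene counts of the original
study suggest.

## Numerical choices and edge cases

* Local-alignment identity is computed over all columns of the aligned
  region, gaps included; hit ambiguity (co-optimal disjoint location)
  makes a segment unmatched, implementing conservatism on tied best hits.
* Boundary projections collapse onto the following aligned run inside
  target gaps and snap within 2 nt; borders beyond a trimmed flank are
  extrapolated gap-free.
* Degenerate inputs: empty transcript sets reject the pair; single-exon
  transcripts are representable but indeterminate; transcripts failing
  frame or translation validation are skipped with a warning at load time;
  a pair of identical genes with identical repertoires yields equal gene
  models, self-pairing, and precision = recall = 1.
* Minus-strand genes are reverse-complemented at load time (recorded in
  `strand_note`), making all downstream logic strand-free. Whether input
  CDS coordinates include the stop codon is normalised at the loader
  boundary: the terminal stop is required and stripped at translation.
* All randomness flows through numpy Generators seeded from the
  configuration, and every stage is deterministic given its inputs;
  re-running the builder yields identical labels.

## Benchmark sizes

The bundled acceptance benchmark uses 50 seeded gene pairs with mixed event
repertoires at 5 % divergence plus 10 divergence-free pairs, and 500-instance
brute-force oracle comparisons for the alignment, BRH and executability
primitives — sizes chosen to exercise every event type and both prediction
directions many times over while keeping a full run in well under a minute
on one CPU.
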