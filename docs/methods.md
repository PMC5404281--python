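# Methods

## Coordinate and strand conventions

All internal coordinates are 0-based half-open; GFF3 I/O converts to the
1-based inclusive file convention at the boundary, and the conversion is an
exact bijection (asserted by round-trip tests). GTF attribute syntax is
accepted on read (dialect auto-detected per line); only GFF3 is written.
Transcript ids must be unique per file — a duplicate is an error rather
than being silently suffixed, because collapse and merge provenance is
tracked by id.

Every occurrence of 5′/3′ language (TSS, TTS, "earlier start", "first
exon", junction-chain suffix) is strand-aware: on the minus strand the TSS
is the genomically rightmost coordinate and the 3′-anchored suffix of a
junction chain is its genomically leftmost run.

## Alignment-based quality scores

The published procedure for read and transcript quality fixes the
numerator and denominator (matches over adapter length; mismatches over
transcript length) but not the aligner. We use a deterministic global
pairwise alignment with match +1, mismatch −1, gap −1 (Biopython's
`PairwiseAligner`); for adapter quality the read's end gaps are free, so
the adapter aligns globally against its best placement inside the read.
A "mismatch" for the error rate is any substituted or gap column. Property
tests check the achieved alignment score against an independent
Needleman–Wunsch dynamic program on short strings; note that co-optimal
alignments can trade matches against indel columns, so the score (not each
count separately) is the invariant quantity.

Thresholds follow the stated wording strictly: a model is kept only when
its error rate is *strictly below* 0.10, so exactly 10 % is removed.

## Internal poly-A screen

The 30-bp genomic window immediately downstream of the putative TTS
(strand-aware; a T-run on the reference for minus-strand models; clipped
rather than skipped at chromosome ends) is scanned for the longest run of
A's containing at most one non-A base, where the run may not begin or end
on the mismatch. A run of ≥ 20 flags the model as possibly truncated by
internal oligo-dT priming. The implementation is a linear two-pointer scan
verified against brute-force enumeration of all window substrings. The
poly-A tail length of a read is the uninterrupted terminal A-run with no
mismatch allowance.

## Collapse semantics

TSSC groups transcripts with identical junction chains and identical TTS;
ECC additionally absorbs any transcript whose chain is a 3′-anchored
suffix of another's (and single-exon transcripts contained in a partner's
3′-terminal exon with matching TTS). Both are computed as the connected
closure of the pairwise relation, so cascades (A and B both suffixes of C
but incomparable to each other) land in one group; the representative is
the longest spliced model, ties broken by lexicographically smaller id.
Collapse tolerances default to 0 (exact junction and TTS match) and are
configurable; the 10/20-nt fuzz applies only to cross-library merging,
where every "difference" threshold is strict (<) per the stated wording.
On merge ties (identical strand-aware starts) the lexicographically
smaller id is kept for determinism.

Gene clustering uses same-strand span overlap of ≥ 1 nt; antisense
overlaps never join genes, which is required for antisense gene pairs to
be countable at all.

A consequence of cascade semantics worth knowing: when two isoforms share
their entire 3′ junction scaffold and differ only 5′-ward, a 5′-degraded
read is genuinely ambiguous between them and ECC merges the two groups.
The simulator's degradation-recovery conditions therefore use
single-isoform genes, where every degraded copy is unambiguous; the
degradation rate is then recovered as (|TSSC| − |ECC|) / n, since each
degraded extra copy survives TSSC (its chain differs) but folds into its
parent under ECC.

## Biotype calling

Coding evidence is combined as a union: a transcript is putatively coding
if it has a protein hit, or CPC labels it coding, or its CPAT probability
is ≥ 0.3 ("scores below 0.3 are noncoding", so exactly 0.3 is coding);
all-missing evidence means noncoding. ORFs are ATG-to-stop in the three
forward frames, stop included, longest per stop; 3′-incomplete frames are
ignored because the premature-termination rule needs the stop position.
The representative ORF is the one with the best protein-hit score (hits
are consumed from the evidence table, keyed by the transcript coordinate
of the ORF's stop, since the homology search itself is external), else the
longest. A coding transcript is reclassified as an NMD candidate when the
last base of its representative stop lies strictly more than 50 nt
upstream of the final splice junction in transcript coordinates (the
55-nt variant is available via `nmd_min_distance`); single-exon
transcripts are never NMD. Noncoding transcripts shorter than 200 nt are
short ncRNA.

lncRNA classes are assigned against the *final* coding set (after NMD
reclassification) with the precedence antisense > sense exonic > sense
intronic > lincRNA. Under this rule a noncoding transcript lying in an
intron of an opposite-strand coding gene is a lincRNA (the antisense class
requires exon-exon overlap); the intronic-antisense relationship is still
reported by the antisense pair classifier. In pair tallies a gene counts
as coding when it contains any coding or NMD transcript.

## Event census

Start-site metrics can be restricted to cap-selected transcripts (the
5′-intact library); termination metrics always use all transcripts. A
"start exon" group is keyed by the first exon's donor boundary (its
junction to exon 2) — boundary-keyed rather than whole-junction-keyed, so
an acceptor shift of exon 2 does not spuriously create a new start-exon
group; termination exons symmetrically by the last exon's acceptor
boundary. Single-exon transcripts group among themselves by span overlap.
Distinct TSS means distinct exact position (wobble counts), which is
exactly why TSE/TTE exist as coarser measures; consequently
multi-TSE ⇒ multi-TSS and multi-TTE ⇒ multi-TTS by construction.

Retained intron: an exon covering another transcript's entire intron.
Skipped exon: an exon fully inside another transcript's intron (by this
definition a sense-intronic lncRNA or an NMD poison exon is a skipped
exon, and the simulator's truth labels account for that). AES/AEE compare
only *overlapping internal* exons, excluding retained-intron exons, and
require one shared strand-aware boundary with the other differing.

"Overlap" for novelty classification and gene-merge detection is exonic,
not span-based, since the exonic/intronic distinction is the point of
those classifications. Per-transcript skipped-exon participation is
reported separately for the skipping and the skipped transcript, since
either convention is defensible.

## The simulator

The generator emulates the statistical structure of a two-tissue,
normalization-based long-read survey of a vertebrate transcriptome:
roughly half of the gene units coding (multi-transcript rate 0.54,
single-exon rate 0.12), lncRNA predominantly single-exon (0.70) and
rarely multi-transcript (0.12), heavy alternative TSS/TTS among
multi-transcript genes (0.95/0.92 with conditional TSE/TTE rates
0.73/0.83), retained introns at 0.35, skipped exons at 0.50, AES/AEE
around 0.2, an NMD isoform rate of 0.20, antisense/sense-overlap partner
rates of a few percent each, 97 % canonical donors, and a 2 % internal
poly-A plant rate. All rates are per-unit Bernoulli draws and every
planted label is recorded as ground truth.

Event isoforms are built by construction to satisfy each event's formal
definition without contaminating the others: structural edits never touch
the first exon's donor or the last exon's acceptor unless the event *is*
a start/termination-exon event; a retained intron is never the 5′-most
intron (that would be indistinguishable from 5′ degradation under ECC)
nor the last (reserved for intron-overlap partners) nor the poison-exon
intron. Whenever a gene's isoforms would otherwise be collapsible
(pure-TSS wobble), each isoform receives its own termination site, spaced
60 nt so poly-A windows stay independent; junction edits are 15 nt,
larger than the merge fuzz.

Coding sequences are frame-consistent across all isoforms of a gene:
internal exon lengths and every structural shift are multiples of three
and the ATG sits in exon 2, so exon boundaries downstream of the start
codon are codon-aligned in every isoform and no spliced variant acquires
an accidental premature stop. CDS interiors are filled with sense codons
excluding in-frame ATG (so the planted start is the only in-frame
initiation site and a premature stop cannot be followed by a long
in-frame competitor ORF); planted splice dinucleotides, start/stop codons
and poly-A runs are fixed positions that codon filling respects. NMD
isoforms gain a 90-nt "poison" cassette exon in the intron after exon 3
carrying an in-frame stop well over 50 nt upstream of the final junction.
Minus-strand genes are built in sense coordinates and reverse-complemented
at placement, so all planting logic is strand-free.

Observed reads are per-transcript copies: copy 0 is always intact;
additional copies lose one or more 5′ exons with the configured
degradation probability (cap-selected copies exempt). Corrupted reads
carry exactly `rate × length` substitutions rather than a binomial draw,
so a planted 12 %-error subset deterministically exceeds the 10 % filter;
background substitution/indel rates, geometric poly-A tails (mean
`polyA_tail_mean`, the survey's observed mean tail being ≈ 40 nt) are
applied per read. Indels are placed uniformly with no homopolymer bias —
a deliberate simplification, so passing tests say nothing about
homopolymer-specific error modes of real long-read chemistry. Other
features of real data the generator does not emulate: expression-level
variation (every transcript yields the same number of copies), mapping
ambiguity (reads inherit exact truth coordinates), chimeras, and
reference-sample sequence divergence.

## Problem sizes and numerical choices

The test suite runs pipeline closure at 500 genes (zero label
disagreement required across structures, gene partition, biotypes and
event flags) and parameter recovery at n = 2000 (99 % binomial CIs);
oracle-equivalence suites use 10³ random instances (10⁴ for the poly-A
window scan). The acceptance script uses the same sizes. Division by a
zero denominator in summary fields yields `None`/`NA`, never zero; an
NMD:coding ratio on a chromosome without coding models is NaN. Unplaced
scaffolds, if present in inputs, are indexed exactly like chromosomes.
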