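# isocensus

Characterizing a transcriptome from long-read (Iso-Seq-style) sequencing
requires a different toolchain than short-read assembly: each read is a
candidate full-length transcript, so the analytical work shifts from exon
chaining to **quality filtering, redundancy collapse and annotation of the
resulting transcript models**. `isocensus` implements that downstream
pipeline as a tested, reusable Python library with a thin CLI, for
bioinformaticians building genome annotations from mapped long-read
transcript models (GFF3/GTF + FASTA).

## What it does

* **QC filters** — adapter-based read quality (matches / adapter length over
  a fit alignment), pre- vs post-mapping error rate
  (mismatch + gap columns / transcript length, models kept only when
  < 10 %), the internal poly-A priming screen (a run of ≥ 20 A's, one
  mismatch allowed, in the 30-bp genomic window downstream of the TTS flags
  a possibly 3′-truncated model), poly-A tail measurement and a canonical
  GT–AG splice-site audit.
* **Redundancy collapse** — Transcription Start Site Collapse (TSSC:
  identical junction chains and 3′ ends, keep the longest model) and Exon
  Cascade Collapse (ECC: TSSC extended to transcripts missing 5′ exons,
  i.e. junction chains that are 3′-anchored suffixes). ECC never yields
  more models than TSSC; the TSSC−ECC gap estimates the 5′-degradation
  rate of a non-cap-selected library.
* **Merging & gene building** — cross-library merging (same exon structure
  within < 10 bp per internal boundary and < 20 bp per transcript end;
  earlier strand-aware start kept), gene clustering by ≥ 1-nt same-strand
  span overlap, and grouping of unmapped reads from pairwise same-strand
  hits.
* **Biotype calling** — union of three coding-evidence sources (protein
  hit, CPC label, CPAT probability with the 0.3 cutoff), ORF finding and
  representative selection, the 50-nt premature-termination (NMD) rule,
  the < 200-nt short-ncRNA split, and positional lncRNA classes
  (lincRNA / antisense / sense exonic / sense intronic).
* **Event census & comparison** — per-gene flags for multiple TSS/TTS,
  alternative start/termination exons (TSE/TTE), retained introns, skipped
  exons and alternative internal exon boundaries (AES/AEE); summary rates
  and ratios; antisense pair classification; novelty classification of one
  annotation against another; and detection of gene-merge ("overhang")
  events where one assembled transcript bridges two or more genes.
* **Synthetic data** — a seeded simulator that plants all of the above with
  recorded ground truth, so the full pipeline is testable end to end
  without any downloads.

## Worked example

```bash
# simulate a small study: genome, truth annotation, observed reads, evidence
isocensus simulate --seed 4 --n-genes 30 --out sim/

# collapse the observed reads and rebuild genes
isocensus collapse --gff sim/observed.gff3 --method ecc --out-gff sim/ecc.gff3
# -> 66 -> 62 models (6.1% collapsed)
isocensus genes --gff sim/ecc.gff3 --out-gff sim/genes.gff3

# screen for internal poly-A priming artifacts and audit splice sites
isocensus qc polya --gff sim/truth.gff3 --genome sim/genome.fa --out sim/polya.tsv
# -> # flagged 1/62 (1.6%)

# assign biotypes and summarize
isocensus biotype --gff sim/truth.gff3 --genome sim/genome.fa \
    --evidence sim/evidence.tsv --out sim/biotypes.tsv
# -> # coding 47 / # lncRNA 14 / # short_ncRNA 1
isocensus summarize --gff sim/truth.gff3 --biotypes sim/biotypes.tsv --all-tss
```

The summary prints one key–value pair per line, e.g.

```
transcripts_per_gene    1.82
pct_multi_tts           100.0
pct_retained_intron     30.0
pct_lncrna_single_exon  85.7
```

`transcripts_per_gene` is the transcript:gene ratio of the annotation;
the `pct_*` fields are rates over multi-transcript genes (how many show
multiple termination sites, a retained intron, …) or over a biotype class
(what fraction of lncRNA transcripts are single-exon). With 4 of the 30
simulated genes drawn as multi-isoform lncRNA-heavy units, the numbers
above match the planted mixture exactly — the test suite asserts this kind
of closure at 500 genes with zero label disagreement.

Each collapse step's reduction is quantified with
`collapse_loss_ratio(pre, post)`; for example a library collapsing from
199,560 to 55,932 models lost `72.0 %` of its models to redundancy and 5′
degradation.

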