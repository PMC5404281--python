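"""Alternative-transcription event census and annotation comparison.

Event definitions (per gene, over its transcripts):

* multiple TSS / TTS: more than one distinct transcription start /
  termination position.  Start-site metrics can be restricted to
  cap-selected transcripts, since only cap-captured libraries guarantee
  intact 5' ends.
* multiple TSE / TTE: more than one start / termination *exon* group, a
  coarsening of TSS/TTS that ignores positional wobble.  First exons are
  grouped by their donor boundary (the junction to exon 2) and last exons
  by their acceptor boundary; single-exon transcripts group among
  themselves by span overlap.
* retained intron: an exon fully spanning another transcript's intron.
* skipped exon: an exon lying fully inside another transcript's intron.
* alternative exon start / end (AES / AEE): two overlapping *internal*
  exons sharing their 3' (AES) or 5' (AEE) boundary while differing at the
  other, retained-intron exons excluded.  Boundaries are read strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .biotype import BiotypeCall
from .model import Annotation, GeneModel, GenomicInterval, TranscriptModel
from .qc import postmap_error_rate

EVENT_NAMES = (
    "multi_TSS",
    "multi_TSE",
    "multi_TTS",
    "multi_TTE",
    "retained_intron",
    "skipped_exon",
    "AES",
    "AEE",
)


@dataclass
class EventCensus:
    gene_id: str
    n_transcripts: int
    n_tss_eligible: int
    flags: Dict[str, bool]
    per_transcript: Dict[str, Dict[str, bool]]
    stse: bool = False


@dataclass(frozen=True)
class OverlapClass:
    transcript_id: str
    coding: bool
    exonic_antisense: bool
    intronic_antisense: bool
    intronic_sense: bool

    @property
    def intergenic(self) -> bool:
        return not (
            self.exonic_antisense or self.intronic_antisense or self.intronic_sense
        )


@dataclass(frozen=True)
class GeneMergeEvent:
    query_transcript_id: str
    ref_gene_ids: Tuple[str, ...]

    @property
    def is_overhang(self) -> bool:
        return len(self.ref_gene_ids) == 2


def _donor_boundary(t: TranscriptModel) -> int:
    """First exon's junction boundary to exon 2 (strand-aware donor side)."""
    return t.exons[0].end if t.strand == "+" else t.exons[-1].start


def _acceptor_boundary(t: TranscriptModel) -> int:
    """Last exon's junction boundary to the penultimate exon."""
    return t.exons[-1].start if t.strand == "+" else t.exons[0].end


def _end_exon_groups(
    transcripts: Sequence[TranscriptModel], which: str
) -> int:
    """Number of start/termination-exon groups among *transcripts*."""
    keys: Set[Tuple] = set()
    singles = [t for t in transcripts if t.n_exons == 1]
    for t in transcripts:
        if t.n_exons == 1:
            continue
        if which == "start":
            keys.add(("J", _donor_boundary(t)))
        else:
            keys.add(("J", _acceptor_boundary(t)))
    # single-exon transcripts form their own groups, clustered by span overlap
    singles.sort(key=lambda t: t.span.start)
    n_single_groups = 0
    reach = None
    for t in singles:
        if reach is None or t.span.start >= reach:
            n_single_groups += 1
            reach = t.span.end
        else:
            reach = max(reach, t.span.end)
    return len(keys) + n_single_groups


def census_gene(
    gene: GeneModel, cap_selected_only_for_TSS: bool = True
) -> EventCensus:
    """Compute the alternative-transcription event flags for one gene."""
    ts = list(gene.transcripts)
    eligible = (
        [t for t in ts if t.cap_selected] if cap_selected_only_for_TSS else ts
    )
    multi = len(ts) > 1

    flags = {name: False for name in EVENT_NAMES}
    per_t: Dict[str, Dict[str, bool]] = {
        t.id: {
            "retained_intron": False,
            "skipped_exon_skipped": False,
            "skipped_exon_skipping": False,
            "AES": False,
            "AEE": False,
        }
        for t in ts
    }

    if multi and len(eligible) > 1:
        flags["multi_TSS"] = len({t.tss for t in eligible}) > 1
        flags["multi_TSE"] = _end_exon_groups(eligible, "start") > 1
    if multi:
        flags["multi_TTS"] = len({t.tts for t in ts}) > 1
        flags["multi_TTE"] = _end_exon_groups(ts, "end") > 1

    # retained introns and skipped exons
    retained_exons: Set[Tuple[str, int, int]] = set()
    for t in ts:
        for u in ts:
            if t is u:
                continue
            for e in t.exons:
                for intron in u.introns:
                    if e.start <= intron.start and intron.end <= e.end:
                        flags["retained_intron"] = True
                        per_t[t.id]["retained_intron"] = True
                        retained_exons.add((t.id, e.start, e.end))
                    if intron.start <= e.start and e.end <= intron.end:
                        flags["skipped_exon"] = True
                        per_t[t.id]["skipped_exon_skipped"] = True
                        per_t[u.id]["skipped_exon_skipping"] = True

    # AES / AEE over internal exons, retained-intron exons excluded
    def internal_exons(t: TranscriptModel):
        for e in t.exons[1:-1]:
            if (t.id, e.start, e.end) not in retained_exons:
                yield e

    for i, t in enumerate(ts):
        for u in ts[i + 1 :]:
            for e in internal_exons(t):
                for f in internal_exons(u):
                    if not e.overlaps(f):
                        continue
                    if t.strand == "+":
                        e5, e3, f5, f3 = e.start, e.end, f.start, f.end
                    else:
                        e5, e3, f5, f3 = e.end, e.start, f.end, f.start
                    if e3 == f3 and e5 != f5:
                        flags["AES"] = True
                        per_t[t.id]["AES"] = True
                        per_t[u.id]["AES"] = True
                    if e5 == f5 and e3 != f3:
                        flags["AEE"] = True
                        per_t[t.id]["AEE"] = True
                        per_t[u.id]["AEE"] = True

    stse = len(ts) == 1 and ts[0].n_exons == 1
    return EventCensus(
        gene_id=gene.id,
        n_transcripts=len(ts),
        n_tss_eligible=len(eligible),
        flags=flags,
        per_transcript=per_t,
        stse=stse,
    )


def census_annotation(
    annotation: Annotation, cap_selected_only_for_TSS: bool = True
) -> Dict[str, EventCensus]:
    return {
        g.id: census_gene(g, cap_selected_only_for_TSS) for g in annotation.genes
    }


# -- summary ratios -------------------------------------------------------


def pct(part: float, whole: float, ndigits: int = 1) -> Optional[float]:
    """Percentage to the given precision; None when the denominator is zero."""
    if whole == 0:
        return None
    return round(100.0 * part / whole, ndigits)


def ratio(numerator: float, denominator: float, ndigits: int = 2) -> Optional[float]:
    if denominator == 0:
        return None
    return round(numerator / denominator, ndigits)


def summarize_annotation(
    annotation: Annotation,
    census: Dict[str, EventCensus],
    biotypes: Dict[str, BiotypeCall],
) -> Dict[str, Optional[float]]:
    """Derived annotation-level rates and ratios.

    Percentages are reported to one decimal and ratios to two; fields with a
    zero denominator come back as None.  Start-site percentages are computed
    over multi-transcript genes with at least two TSS-eligible transcripts.
    """
    n_t = len(annotation.transcripts)
    n_g = len(annotation.genes)
    single_t_genes = sum(1 for c in census.values() if c.n_transcripts == 1)
    mt_genes = n_g - single_t_genes
    mt_transcripts = n_t - single_t_genes
    stse_genes = sum(1 for c in census.values() if c.stse)

    mt = [c for c in census.values() if c.n_transcripts > 1]
    tss_eligible = [c for c in mt if c.n_tss_eligible > 1]

    def gene_is(biotype: str, g: GeneModel) -> bool:
        return any(biotypes[t.id].biotype == biotype for t in g.transcripts)

    coding_genes = [g for g in annotation.genes if gene_is("coding", g)]
    lnc_genes = [
        g
        for g in annotation.genes
        if gene_is("lncRNA", g) and not gene_is("coding", g)
    ]
    coding_mt = sum(1 for g in coding_genes if len(g.transcripts) > 1)
    lnc_mt = sum(1 for g in lnc_genes if len(g.transcripts) > 1)

    coding_t = [t.id for t in annotation if biotypes[t.id].biotype == "coding"]
    lnc_t = [t.id for t in annotation if biotypes[t.id].biotype == "lncRNA"]
    coding_single_exon = sum(
        1 for tid in coding_t if annotation.transcripts[tid].n_exons == 1
    )
    lnc_single_exon = sum(
        1 for tid in lnc_t if annotation.transcripts[tid].n_exons == 1
    )

    return {
        "n_transcripts": n_t,
        "n_genes": n_g,
        "transcripts_per_gene": ratio(n_t, n_g),
        "single_transcript_genes": single_t_genes,
        "multi_transcript_genes": mt_genes,
        "transcripts_per_mt_gene": ratio(mt_transcripts, mt_genes),
        "stse_genes": stse_genes,
        "stse_to_mt_ratio": ratio(stse_genes, mt_genes),
        "pct_multi_tss": pct(
            sum(c.flags["multi_TSS"] for c in tss_eligible), len(tss_eligible)
        ),
        "pct_multi_tse": pct(
            sum(c.flags["multi_TSE"] for c in tss_eligible), len(tss_eligible)
        ),
        "pct_multi_tts": pct(sum(c.flags["multi_TTS"] for c in mt), len(mt)),
        "pct_multi_tte": pct(sum(c.flags["multi_TTE"] for c in mt), len(mt)),
        "pct_retained_intron": pct(
            sum(c.flags["retained_intron"] for c in mt), len(mt)
        ),
        "pct_skipped_exon": pct(sum(c.flags["skipped_exon"] for c in mt), len(mt)),
        "pct_genes_with_aes": pct(sum(c.flags["AES"] for c in mt), len(mt)),
        "pct_genes_with_aee": pct(sum(c.flags["AEE"] for c in mt), len(mt)),
        "pct_genes_no_aes": pct(
            len(mt) - sum(c.flags["AES"] for c in mt), len(mt)
        ),
        "pct_genes_no_aee": pct(
            len(mt) - sum(c.flags["AEE"] for c in mt), len(mt)
        ),
        "pct_coding_genes_mt": pct(coding_mt, len(coding_genes)),
        "pct_lncrna_genes_mt": pct(lnc_mt, len(lnc_genes)),
        "pct_coding_single_exon": pct(coding_single_exon, len(coding_t)),
        "pct_lncrna_single_exon": pct(lnc_single_exon, len(lnc_t)),
    }


# -- antisense classification ---------------------------------------------


def _exon_exon_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    return any(ea.overlaps(eb) for ea in a.exons for eb in b.exons)


def _exon_in_intron(a: TranscriptModel, b: TranscriptModel) -> bool:
    return any(ib.contains(ea) for ea in a.exons for ib in b.introns)


def antisense_classify(
    annotation: Annotation, biotypes: Dict[str, BiotypeCall]
) -> Dict[str, pd.DataFrame]:
    """Classify opposite-strand transcript overlaps as exonic or intronic.

    An exonic antisense pair shares >=1 nt of exon sequence on opposite
    strands; an intronic antisense pair has an exon of one transcript fully
    inside an intron of the other (and is not exonic).  Gene pairs are
    deduplicated and tallied by coding-class combination, where a gene
    counts as coding when it contains any coding or NMD transcript.
    """
    t_rows: List[dict] = []
    gene_pairs: Dict[str, Set[Tuple[str, str]]] = {"exonic": set(), "intronic": set()}
    seen: Set[Tuple[str, str]] = set()
    for t in annotation:
        rev = GenomicInterval(
            t.span.chrom, t.span.start, t.span.end, "-" if t.strand == "+" else "+"
        )
        for u in annotation.overlap_query(rev, same_strand=True):
            key = tuple(sorted((t.id, u.id)))
            if key in seen:
                continue
            seen.add(key)
            exonic = _exon_exon_overlap(t, u)
            intronic = not exonic and (
                _exon_in_intron(t, u) or _exon_in_intron(u, t)
            )
            if not exonic and not intronic:
                continue
            kind = "exonic" if exonic else "intronic"
            t_rows.append(
                {"transcript_a": key[0], "transcript_b": key[1], "kind": kind}
            )
            gp = tuple(
                sorted((annotation.gene_of(t.id).id, annotation.gene_of(u.id).id))
            )
            gene_pairs[kind].add(gp)

    coding_gene = {
        g.id: any(biotypes[t.id].biotype in ("coding", "NMD") for t in g.transcripts)
        for g in annotation.genes
    }

    def gene_coding(gid: str) -> bool:
        return coding_gene[gid]

    g_rows: List[dict] = []
    for kind, pairs in gene_pairs.items():
        for ga, gb in sorted(pairs):
            combo = {gene_coding(ga), gene_coding(gb)}
            if combo == {True}:
                label = "coding-coding"
            elif combo == {False}:
                label = "noncoding-noncoding"
            else:
                label = "coding-noncoding"
            g_rows.append({"gene_a": ga, "gene_b": gb, "kind": kind, "combo": label})

    return {
        "transcript_pairs": pd.DataFrame(
            t_rows, columns=["transcript_a", "transcript_b", "kind"]
        ),
        "gene_pairs": pd.DataFrame(
            g_rows, columns=["gene_a", "gene_b", "kind", "combo"]
        ),
    }


# -- annotation-to-annotation comparison ----------------------------------


def novelty_classify(
    query: Annotation,
    reference: Annotation,
    biotypes: Dict[str, BiotypeCall],
) -> Tuple[List[OverlapClass], pd.DataFrame]:
    """Classify query transcripts against a reference annotation.

    A query transcript is *novel* iff it has no same-strand exonic overlap
    with any reference transcript.  Novel transcripts are assigned the
    (exonic antisense, intronic antisense, intronic sense) boolean pattern
    against the reference, crossed with their coding class; the counts table
    covers every observed pattern.  Exonic antisense takes precedence over
    intronic antisense.
    """
    classes: List[OverlapClass] = []
    for t in query:
        hits = reference.overlap_query(
            GenomicInterval(t.span.chrom, t.span.start, t.span.end, t.strand)
        )
        sense = [u for u in hits if u.strand == t.strand]
        anti = [u for u in hits if u.strand != t.strand]
        if any(_exon_exon_overlap(t, u) for u in sense):
            continue  # known: sense exonic overlap with the reference
        ea = any(_exon_exon_overlap(t, u) for u in anti)
        ia = (not ea) and any(
            _exon_in_intron(t, u) or _exon_in_intron(u, t) for u in anti
        )
        is_ = any(_exon_in_intron(t, u) or _exon_in_intron(u, t) for u in sense)
        coding = biotypes[t.id].biotype in ("coding", "NMD")
        classes.append(OverlapClass(t.id, coding, ea, ia, is_))

    rows = []
    patterns: Dict[Tuple[bool, bool, bool, bool], int] = {}
    for c in classes:
        key = (c.coding, c.exonic_antisense, c.intronic_antisense, c.intronic_sense)
        patterns[key] = patterns.get(key, 0) + 1
    for key in sorted(patterns, reverse=True):
        coding, ea, ia, is_ = key
        rows.append(
            {
                "coding_class": "coding RNA" if coding else "ncRNA",
                "exonic_antisense": ea,
                "intronic_antisense": ia,
                "intronic_sense": is_,
                "n_transcripts": patterns[key],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "coding_class",
            "exonic_antisense",
            "intronic_antisense",
            "intronic_sense",
            "n_transcripts",
        ],
    )
    return classes, table


def detect_gene_merges(
    ref: Annotation, query: Annotation
) -> List[GeneMergeEvent]:
    """Find query transcripts that bridge two or more reference genes.

    A reference gene is hit when the query transcript has same-strand exonic
    overlap with any of its transcripts.  Events with exactly two reference
    genes are "overhang" events (one upstream and one downstream gene
    represented as a single merged model); three or more are general gene
    merges.  Hit genes are listed 5'-to-3' along the query transcript.
    """
    events: List[GeneMergeEvent] = []
    for t in sorted(query, key=lambda t: (t.chrom, t.span.start, t.id)):
        hit_genes: Dict[str, int] = {}
        for u in ref.overlap_query(
            GenomicInterval(t.span.chrom, t.span.start, t.span.end, t.strand),
            same_strand=True,
        ):
            if _exon_exon_overlap(t, u):
                g = ref.gene_of(u.id)
                pos = g.span.start
                if g.id not in hit_genes:
                    hit_genes[g.id] = pos
        if len(hit_genes) >= 2:
            ordered = sorted(hit_genes, key=lambda gid: hit_genes[gid])
            if t.strand == "-":
                ordered.reverse()
            events.append(GeneMergeEvent(t.id, tuple(ordered)))
    return events


def mapping_quality_percent(transcript_seq: str, projected_seq: str) -> float:
    """Matching nucleotides over transcript length for a cross-genome mapping."""
    score = postmap_error_rate(transcript_seq, projected_seq)
    return min(1.0, score.matches / score.denom_len)
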