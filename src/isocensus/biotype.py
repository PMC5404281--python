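"""Coding potential, ORF selection, NMD prediction and lncRNA classification.

The coding call combines three external evidence sources (protein homology
hit, CPC label, CPAT probability) as a union: any positive evidence makes
the transcript putatively coding, and a transcript with no evidence at all
is noncoding.  Coding transcripts are then screened for premature
termination codons: a representative open reading frame whose stop codon
lies more than 50 nt upstream of the final splice junction marks the
transcript as a nonsense-mediated-decay (NMD) candidate.  Noncoding
transcripts shorter than 200 nt are short ncRNA; the rest are lncRNA,
subclassified by their positional relationship to the final coding set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .model import Annotation, GenomicInterval, TranscriptModel, spliced_sequence

STOP_CODONS = ("TAA", "TAG", "TGA")
LNC_CLASSES = ("lincRNA", "antisense", "sense_exonic", "sense_intronic")


@dataclass(frozen=True)
class CodingEvidence:
    transcript_id: str
    has_protein_hit: bool = False
    cpc_label: str = "missing"  # coding / noncoding / missing
    cpat_score: Optional[float] = None


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame in transcript coordinates (0-based half-open).

    ``start``..``end`` spans ATG through the stop codon inclusive, so the
    length is divisible by three and the last base of the stop codon sits at
    ``end - 1``.
    """

    frame: int
    start: int
    end: int
    hit_score: Optional[float] = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BiotypeCall:
    transcript_id: str
    biotype: str  # coding / lncRNA / short_ncRNA / NMD
    lncRNA_class: Optional[str] = None


def find_orfs(seq: str, n_best: int = 3) -> List[OrfCall]:
    """Locate the longest open reading frames in the three forward frames.

    An ORF runs from an ATG to the first in-frame stop codon (stop
    included); per stop codon only the longest ORF (earliest usable ATG) is
    kept.  3'-incomplete reading frames without a stop are ignored, since
    downstream premature-termination logic needs the stop position.  Returns
    up to *n_best* calls in descending length, ties broken by (frame,
    start).
    """
    s = seq.upper()
    orfs: List[OrfCall] = []
    for frame in range(3):
        first_atg: Optional[int] = None
        for pos in range(frame, len(s) - 2, 3):
            codon = s[pos : pos + 3]
            if codon == "ATG" and first_atg is None:
                first_atg = pos
            elif codon in STOP_CODONS:
                if first_atg is not None:
                    orfs.append(OrfCall(frame=frame, start=first_atg, end=pos + 3))
                first_atg = None
    orfs.sort(key=lambda o: (-o.length, o.frame, o.start))
    return orfs[:n_best]


def select_representative_orf(orfs: Sequence[OrfCall]) -> OrfCall:
    """Pick the ORF with the best protein hit, else the longest.

    Ties on hit score fall back to the longer ORF, then the 5'-most start.
    """
    if not orfs:
        raise ValueError("no_orf")
    scored = [o for o in orfs if o.hit_score is not None]
    pool = scored if scored else list(orfs)
    key = (
        (lambda o: (-o.hit_score, -o.length, o.start))
        if scored
        else (lambda o: (-o.length, o.start))
    )
    return sorted(pool, key=key)[0]


def classify_coding(evidence: CodingEvidence, cpat_cutoff: float = 0.3) -> str:
    """Combine the three evidence sources into a coding/noncoding call.

    Coding iff a protein hit exists, OR CPC labels the transcript coding, OR
    the CPAT probability is at least the cutoff (scores *below* 0.3 are
    noncoding, so exactly 0.3 is coding).  All-missing evidence means
    noncoding.
    """
    if evidence.cpat_score is not None and not 0.0 <= evidence.cpat_score <= 1.0:
        raise ValueError(f"cpat_score out of range: {evidence.cpat_score}")
    if evidence.has_protein_hit:
        return "coding"
    if evidence.cpc_label == "coding":
        return "coding"
    if evidence.cpat_score is not None and evidence.cpat_score >= cpat_cutoff:
        return "coding"
    return "noncoding"


def final_junction_position(transcript: TranscriptModel) -> Optional[int]:
    """Transcript coordinate of the 3'-most exon-exon junction (None if single-exon)."""
    if transcript.n_exons < 2:
        return None
    return transcript.length - len(transcript.last_exon)


def predict_nmd(
    transcript: TranscriptModel, orf: OrfCall, min_distance: int = 50
) -> bool:
    """Apply the 50-nt premature-termination rule.

    True iff the transcript is multi-exon and the last base of the
    representative ORF's stop codon lies strictly more than *min_distance*
    nt upstream of the final splice junction (both in transcript
    coordinates).  A stop ending exactly 50 nt upstream is not NMD.
    """
    if orf.end > transcript.length:
        raise ValueError("ORF extends past transcript end")
    junction = final_junction_position(transcript)
    if junction is None:
        return False
    return junction - orf.end > min_distance


def _exon_exon_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    return any(ea.overlaps(eb) for ea in a.exons for eb in b.exons)


def _exon_in_intron(a: TranscriptModel, b: TranscriptModel) -> bool:
    """True if some exon of *a* lies fully inside an intron of *b*."""
    return any(ib.contains(ea) for ea in a.exons for ib in b.introns)


def classify_lncrna(
    transcript: TranscriptModel, coding: Annotation
) -> str:
    """Positional lncRNA class against the coding transcript set.

    Precedence: antisense (exon overlaps a coding exon on the opposite
    strand) > sense_exonic (same-strand exonic overlap) > sense_intronic
    (span within a coding transcript's intron, or a coding transcript within
    one of this transcript's introns, same strand) > lincRNA.
    """
    if transcript.length < 200:
        raise ValueError("use short_ncRNA path")
    candidates = coding.overlap_query(transcript.span)
    anti = [c for c in candidates if c.strand != transcript.strand]
    sense = [c for c in candidates if c.strand == transcript.strand]
    if any(_exon_exon_overlap(transcript, c) for c in anti):
        return "antisense"
    if any(_exon_exon_overlap(transcript, c) for c in sense):
        return "sense_exonic"
    for c in sense:
        if any(ic.contains(transcript.span) for ic in c.introns):
            return "sense_intronic"
        if any(it.contains(c.span) for it in transcript.introns):
            return "sense_intronic"
    return "lincRNA"


def _evidence_from_row(row) -> CodingEvidence:
    cpat = row.get("cpat_score")
    if cpat is not None and (isinstance(cpat, float) and math.isnan(cpat)):
        cpat = None
    cpc = row.get("cpc_label", "missing")
    if not isinstance(cpc, str) or cpc in ("", "NA", "nan"):
        cpc = "missing"
    return CodingEvidence(
        transcript_id=row["transcript_id"],
        has_protein_hit=bool(int(row.get("has_protein_hit", 0) or 0)),
        cpc_label=cpc,
        cpat_score=float(cpat) if cpat is not None else None,
    )


def biotype_pipeline(
    annotation: Annotation,
    evidence: pd.DataFrame,
    genome=None,
    cpat_cutoff: float = 0.3,
    nmd_min_distance: int = 50,
) -> Dict[str, BiotypeCall]:
    """Assign every transcript a mutually exclusive biotype.

    Order of application: evidence-based coding call; the coding branch runs
    ORF finding, representative selection (using per-ORF protein-hit scores
    from the evidence table when present, keyed by the transcript coordinate
    of the ORF stop) and the premature-termination rule, reclassifying NMD
    candidates; the noncoding branch splits at 200 nt into short ncRNA and
    lncRNA, the latter classified positionally against the final coding set.
    Transcript sequences come from ``genome`` unless carried on the models.
    """
    ev_by_id: Dict[str, dict] = {}
    for _, row in evidence.iterrows():
        ev_by_id[row["transcript_id"]] = dict(row)

    coding_ids: Set[str] = set()
    for t in annotation:
        row = ev_by_id.get(t.id)
        ev = _evidence_from_row(row) if row else CodingEvidence(t.id)
        if classify_coding(ev, cpat_cutoff) == "coding":
            coding_ids.add(t.id)

    calls: Dict[str, BiotypeCall] = {}
    nmd_ids: Set[str] = set()
    for tid in sorted(coding_ids):
        t = annotation.transcripts[tid]
        seq = t.sequence if t.sequence else spliced_sequence(genome, t)
        orfs = find_orfs(seq)
        row = ev_by_id.get(tid, {})
        hit_end = row.get("orf_hit_end")
        hit_score = row.get("orf_hit_score")
        if hit_end is not None and not (
            isinstance(hit_end, float) and math.isnan(hit_end)
        ):
            hit_end = int(hit_end)
            orfs = [
                OrfCall(o.frame, o.start, o.end, float(hit_score))
                if o.end == hit_end
                else o
                for o in orfs
            ]
        if not orfs:
            calls[tid] = BiotypeCall(tid, "coding")
            continue
        rep = select_representative_orf(orfs)
        if predict_nmd(t, rep, nmd_min_distance):
            calls[tid] = BiotypeCall(tid, "NMD")
            nmd_ids.add(tid)
        else:
            calls[tid] = BiotypeCall(tid, "coding")

    final_coding = [
        annotation.transcripts[tid] for tid in sorted(coding_ids - nmd_ids)
    ]
    coding_annot = Annotation.from_transcripts(final_coding)

    for t in annotation:
        if t.id in coding_ids:
            continue
        if t.length < 200:
            calls[t.id] = BiotypeCall(t.id, "short_ncRNA")
        else:
            calls[t.id] = BiotypeCall(
                t.id, "lncRNA", classify_lncrna(t, coding_annot)
            )
    return calls


def nmd_coding_ratio(
    calls: Dict[str, BiotypeCall], annotation: Annotation, level: str = "transcript"
) -> pd.DataFrame:
    """Per-chromosome NMD:coding ratio at transcript or gene level.

    At gene level a gene counts once for every category it contains.  A
    chromosome with no coding models gets an undefined (NaN) ratio rather
    than zero.
    """
    if level not in ("transcript", "gene"):
        raise ValueError("level must be 'transcript' or 'gene'")
    counts: Dict[str, Dict[str, int]] = {}
    if level == "transcript":
        for t in annotation:
            b = calls[t.id].biotype
            if b in ("NMD", "coding"):
                c = counts.setdefault(t.chrom, {"NMD": 0, "coding": 0})
                c[b] += 1
    else:
        for g in annotation.genes:
            cats = {calls[t.id].biotype for t in g.transcripts}
            c = counts.setdefault(g.chrom, {"NMD": 0, "coding": 0})
            for b in ("NMD", "coding"):
                if b in cats:
                    c[b] += 1
    rows = []
    for chrom in sorted(counts):
        nmd, cod = counts[chrom]["NMD"], counts[chrom]["coding"]
        rows.append(
            {
                "chrom": chrom,
                "nmd": nmd,
                "coding": cod,
                "ratio": nmd / cod if cod else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "nmd", "coding", "ratio"])
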