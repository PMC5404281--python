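"""Sequence-level quality control for long-read transcript models.

Implements the filtering stages applied between genome mapping and
redundancy collapse: adapter-based read quality, pre- vs post-mapping error
rate, the internal poly-A priming artifact screen, poly-A tail measurement,
and the canonical GT-AG splice-site audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from Bio import Align

from .model import TranscriptModel, reverse_complement


@dataclass(frozen=True)
class QualityScore:
    """Alignment-derived quality of a read.

    ``matches`` counts aligned identical positions, ``mismatches`` counts
    substituted columns plus gap columns, and ``denom_len`` is the length used
    as denominator (the adapter length for read quality, the pre-mapped
    transcript length for post-mapping error).
    """

    matches: int
    mismatches: int
    denom_len: int

    @property
    def value(self) -> float:
        """Quality fraction, clipped to [0, 1]."""
        return min(1.0, max(0.0, self.matches / self.denom_len))

    @property
    def error_rate(self) -> float:
        return self.mismatches / self.denom_len


@dataclass(frozen=True)
class PolyAFlag:
    """Result of the internal poly-A priming screen for one transcript."""

    window_seq: str
    longest_run: int
    flagged: bool


@dataclass
class SpliceSiteAudit:
    """GT-AG audit across a set of multi-exon transcripts."""

    per_intron: Dict[str, List[Tuple[str, str, str]]]  # tid -> (donor, acceptor, label)
    all_canonical: Dict[str, bool]
    canonical_fraction: float


def _global_aligner() -> Align.PairwiseAligner:
    # Deterministic scoring (match +1, mismatch -1, gap -1); the published
    # procedure fixed only the mismatch count and the denominator.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def _fit_aligner() -> Align.PairwiseAligner:
    # Adapter ("query") aligned globally against its best placement inside
    # the read ("target"): end gaps on the read are free.
    aligner = _global_aligner()
    try:
        aligner.end_deletion_score = 0  # read bases flanking the adapter are free
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0
    return aligner


def _counts(alignment) -> Tuple[int, int, int]:
    c = alignment.counts()
    return c.identities, c.mismatches, c.gaps


def adapter_quality(roi_seq: str, adapter_seq: str) -> QualityScore:
    """Quality of a read-of-insert from its embedded adapter copy.

    The adapter is globally aligned to its best-scoring placement within the
    read; quality = aligned matches / adapter length, so indels in the
    adapter copy lower the score through lost matches while the denominator
    stays fixed.
    """
    if not adapter_seq:
        raise ValueError("adapter sequence must be non-empty")
    if not roi_seq:
        raise ValueError("ROI sequence must be non-empty")
    alignment = _fit_aligner().align(roi_seq.upper(), adapter_seq.upper())[0]
    # End columns where the read runs past the adapter are free target end
    # gaps; restrict counting to the adapter's aligned extent.
    identities, mismatches, gaps = _aligned_extent_counts(alignment)
    return QualityScore(identities, mismatches + gaps, len(adapter_seq))


def _aligned_extent_counts(alignment) -> Tuple[int, int, int]:
    """Identities/mismatches/gap columns within the adapter's aligned extent.

    The free end gaps on the read flanks are excluded: only columns where
    the adapter participates (aligned pairs, adapter bases against gaps, and
    read bases inserted between adapter blocks) are counted.
    """
    target = alignment.target
    query = alignment.query
    if len(alignment.aligned[1]) == 0:
        return 0, 0, len(query)
    identities = mismatches = 0
    for (ts, te), (qs, qe) in zip(*alignment.aligned):
        for t, q in zip(range(ts, te), range(qs, qe)):
            if target[t] == query[q]:
                identities += 1
            else:
                mismatches += 1
    qcovered = sum(qe - qs for qs, qe in alignment.aligned[1])
    gaps = len(query) - qcovered  # adapter bases aligned against gaps
    tblocks = alignment.aligned[0]
    for (_, t0e), (t1s, _) in zip(tblocks, tblocks[1:]):
        gaps += t1s - t0e  # read bases inserted inside the adapter copy
    return identities, mismatches, gaps


def postmap_error_rate(pre_seq: str, post_seq: str) -> QualityScore:
    """Error rate between the pre-mapped read and its genome-projected sequence.

    The two sequences are globally aligned; the error rate is
    (substituted columns + gap columns) / pre-mapped length and the quality
    score is its complement.
    """
    if not pre_seq or not post_seq:
        raise ValueError("both sequences must be non-empty")
    alignment = _global_aligner().align(pre_seq.upper(), post_seq.upper())[0]
    identities, mismatches, gaps = _counts(alignment)
    return QualityScore(identities, mismatches + gaps, len(pre_seq))


def filter_by_error_rate(
    transcripts: Iterable[TranscriptModel],
    projected: Dict[str, str],
    threshold: float = 0.10,
) -> Tuple[List[TranscriptModel], List[Tuple[TranscriptModel, str]]]:
    """Partition transcripts by post-mapping error rate.

    A transcript is kept iff its error rate is strictly below *threshold*
    (a rate of exactly 10% is removed under the default).  ``projected`` maps
    transcript id to the genome-projected sequence; transcripts lacking
    either sequence are routed to the removed set with reason
    ``"no_sequence"``.
    """
    kept: List[TranscriptModel] = []
    removed: List[Tuple[TranscriptModel, str]] = []
    for t in transcripts:
        post = projected.get(t.id)
        if not t.sequence or not post:
            removed.append((t, "no_sequence"))
            continue
        score = postmap_error_rate(t.sequence, post)
        if score.error_rate < threshold:
            kept.append(t)
        else:
            removed.append((t, f"error_rate={score.error_rate:.4f}"))
    return kept, removed


def longest_a_run(window: str, allowed_mismatches: int = 1) -> int:
    """Longest run of A in *window* containing at most one non-A base.

    The run may not begin or end on the mismatch, so a lone non-A base never
    extends a run past its flanking As.
    """
    w = window.upper()
    best = 0
    i = 0
    n = len(w)
    non_a_positions: List[int] = []
    j = 0
    for j in range(n):
        if w[j] != "A":
            non_a_positions.append(j)
        while len(non_a_positions) > allowed_mismatches:
            i = non_a_positions.pop(0) + 1
        # trim mismatches from the ends of the candidate run
        s, e = i, j
        while s <= e and w[s] != "A":
            s += 1
        while e >= s and w[e] != "A":
            e -= 1
        if e >= s:
            best = max(best, e - s + 1)
    return best


def internal_polyA_flag(
    genome,
    transcript: TranscriptModel,
    window: int = 30,
    min_run: int = 20,
    allowed_mismatches: int = 1,
) -> PolyAFlag:
    """Screen the genomic window downstream of the TTS for a poly-A run.

    Oligo-dT primers can anneal to genomic A-rich stretches, truncating the
    transcript 3' end; a run of >= *min_run* As (allowing one internal
    mismatch) within the *window* nt immediately downstream of the putative
    TTS flags the model as possibly truncated.  The window is read
    strand-aware (a run of Ts on the reference for minus-strand models) and
    clipped at chromosome ends.
    """
    if transcript.chrom not in genome:
        raise KeyError(f"chromosome {transcript.chrom!r} not in genome")
    chrom_seq = genome[transcript.chrom]
    chrom_len = len(chrom_seq)
    if transcript.strand == "+":
        start = transcript.tts
        seq = str(chrom_seq[start : min(start + window, chrom_len)]).upper()
    else:
        end = transcript.tts
        seq = str(chrom_seq[max(0, end - window) : end]).upper()
        seq = reverse_complement(seq)
    run = longest_a_run(seq, allowed_mismatches)
    return PolyAFlag(window_seq=seq, longest_run=run, flagged=run >= min_run)


def measure_trailing_A(roi_seq: str) -> int:
    """Length of the uninterrupted terminal run of A (no mismatch allowance)."""
    n = 0
    for base in reversed(roi_seq.upper()):
        if base != "A":
            break
        n += 1
    return n


def splice_site_audit(
    genome, transcripts: Iterable[TranscriptModel]
) -> SpliceSiteAudit:
    """Audit donor/acceptor intronic dinucleotides against canonical GT-AG.

    Dinucleotides are strand-corrected so the canonical pair reads GT-AG on
    both strands.  Introns shorter than 4 nt are labelled ``too_short`` and
    transcripts containing one are excluded from the canonical fraction,
    which is computed over multi-exon transcripts whose introns are all
    canonical.
    """
    per_intron: Dict[str, List[Tuple[str, str, str]]] = {}
    all_canonical: Dict[str, bool] = {}
    n_eligible = 0
    n_canon = 0
    for t in transcripts:
        if t.n_exons < 2:
            continue
        chrom_seq = genome[t.chrom]
        labels: List[Tuple[str, str, str]] = []
        usable = True
        canon = True
        for intron in t.introns:
            if len(intron) < 4:
                labels.append(("", "", "too_short"))
                usable = False
                continue
            left = str(chrom_seq[intron.start : intron.start + 2]).upper()
            right = str(chrom_seq[intron.end - 2 : intron.end]).upper()
            if t.strand == "+":
                donor, acceptor = left, right
            else:
                donor, acceptor = (
                    reverse_complement(right),
                    reverse_complement(left),
                )
            is_canon = donor == "GT" and acceptor == "AG"
            labels.append((donor, acceptor, "canonical" if is_canon else "noncanonical"))
            canon = canon and is_canon
        per_intron[t.id] = labels
        if usable:
            all_canonical[t.id] = canon
            n_eligible += 1
            n_canon += int(canon)
    fraction = n_canon / n_eligible if n_eligible else float("nan")
    return SpliceSiteAudit(per_intron, all_canonical, fraction)
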