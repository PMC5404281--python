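"""Core domain types for transcript-level genome annotation.

Coordinates are 0-based, half-open throughout the package; GFF3 I/O converts
to/from the 1-based inclusive convention at the file boundary.  All 5'/3'
language (TSS, TTS, "earlier start") is strand-aware: on the minus strand the
transcription start site is the genomically *rightmost* coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one nucleotide."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """A stranded multi-exon transcript model.

    ``exons`` are sorted by genomic start, non-overlapping, and all on one
    chromosome and strand.  ``sequence`` optionally carries the pre-mapping
    read sequence (5'->3' in transcript orientation).
    """

    id: str
    exons: Tuple[GenomicInterval, ...]
    source_library: str = ""
    cap_selected: bool = False
    sequence: Optional[str] = None
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        exons = tuple(self.exons)
        if not exons:
            raise ValueError(f"transcript {self.id} has no exons")
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"transcript {self.id}: exons span chrom/strand")
        exons = tuple(sorted(exons, key=lambda e: e.start))
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.id}: exons overlap or touch "
                    f"({a.start},{a.end}) / ({b.start},{b.end})"
                )
        object.__setattr__(self, "exons", exons)

    # -- basic geometry ------------------------------------------------

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @cached_property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        """Spliced (exonic) length in nucleotides."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    # -- strand-aware landmarks ----------------------------------------

    @property
    def tss(self) -> int:
        """Transcription start site (5'-most genomic coordinate)."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def tts(self) -> int:
        """Transcription termination site (3'-most genomic coordinate)."""
        return self.exons[-1].end if self.strand == "+" else self.exons[0].start

    @property
    def first_exon(self) -> GenomicInterval:
        """5'-most exon."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def last_exon(self) -> GenomicInterval:
        """3'-most exon."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @cached_property
    def junctions(self) -> Tuple[Tuple[int, int], ...]:
        """Splice junction chain in genomic order: (exon_end, next_exon_start)."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @cached_property
    def introns(self) -> Tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, end, start, self.strand)
            for end, start in self.junctions
        )

    def junctions_3prime_order(self) -> Tuple[Tuple[int, int], ...]:
        """Junction chain ordered from the 3' end of the transcript inward."""
        j = self.junctions
        return tuple(reversed(j)) if self.strand == "+" else j


@dataclass
class GeneModel:
    """A gene: connected component of same-strand, >=1-nt overlapping transcripts."""

    id: str
    transcripts: Tuple[TranscriptModel, ...]
    span: GenomicInterval = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.id} has no transcripts")
        strands = {t.strand for t in self.transcripts}
        chroms = {t.chrom for t in self.transcripts}
        if len(strands) != 1 or len(chroms) != 1:
            raise ValueError(f"gene {self.id}: mixed chrom/strand")
        if self.span is None:
            self.span = GenomicInterval(
                self.transcripts[0].chrom,
                min(t.span.start for t in self.transcripts),
                max(t.span.end for t in self.transcripts),
                self.transcripts[0].strand,
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand


@dataclass
class RoiRecord:
    """A circular-consensus read-of-insert with its adapter-derived quality."""

    id: str
    sequence: str
    adapter_quality: float = 1.0
    polyA_tail_len: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.adapter_quality <= 1.0:
            raise ValueError("adapter_quality must be in [0, 1]")
        if self.polyA_tail_len < 0:
            raise ValueError("polyA_tail_len must be >= 0")


class Annotation:
    """A set of genes with an interval index supporting overlap queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: List[GeneModel] = list(genes)
        self.transcripts: Dict[str, TranscriptModel] = {}
        self._gene_of: Dict[str, GeneModel] = {}
        for g in self.genes:
            for t in g.transcripts:
                if t.id in self.transcripts:
                    raise ValueError(f"duplicate transcript id {t.id!r}")
                self.transcripts[t.id] = t
                self._gene_of[t.id] = g
        self._index: Dict[str, IntervalTree] = {}
        for t in self.transcripts.values():
            tree = self._index.setdefault(t.chrom, IntervalTree())
            tree.addi(t.span.start, t.span.end, t.id)

    # -- construction --------------------------------------------------

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptModel]) -> "Annotation":
        """Build an annotation by clustering transcripts into genes.

        Genes are connected components of the same-strand, same-chromosome
        span-overlap (>=1 nt) graph; opposite-strand overlaps never join genes.
        Gene ids are deterministic, ordered by (chrom, span start, strand).
        """
        from .collapse import cluster_genes  # local import avoids a cycle

        return cls(cluster_genes(transcripts))

    # -- queries -------------------------------------------------------

    def gene_of(self, transcript_id: str) -> GeneModel:
        return self._gene_of[transcript_id]

    def overlap_query(
        self, interval: GenomicInterval, same_strand: bool = False
    ) -> List[TranscriptModel]:
        """Transcripts whose span shares >=1 nt with *interval*.

        Unknown chromosomes yield an empty list.  With ``same_strand`` the
        result is restricted to the interval's strand.
        """
        tree = self._index.get(interval.chrom)
        if tree is None:
            return []
        hits = [self.transcripts[iv.data] for iv in tree.overlap(interval.start, interval.end)]
        if same_strand:
            hits = [t for t in hits if t.strand == interval.strand]
        return sorted(hits, key=lambda t: (t.span.start, t.id))

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())


def spliced_sequence(genome, transcript: TranscriptModel) -> str:
    """Extract the spliced transcript sequence (5'->3') from a genome mapping.

    *genome* is any mapping of chromosome name to sequence string (a plain
    dict or a pyfaidx.Fasta both work).
    """
    chrom_seq = genome[transcript.chrom]
    parts = [str(chrom_seq[e.start : e.end]) for e in transcript.exons]
    seq = "".join(parts).upper()
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
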