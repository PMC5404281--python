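"""Redundancy collapse, cross-library merging and gene clustering.

Two collapse modes reduce mapped transcript models within a library:

* TSS collapse (TSSC): transcripts with identical splice-junction chains and
  identical 3' ends but varying start sites reduce to the longest model.
* Exon cascade collapse (ECC): TSSC extended to 5'-degraded models — a
  transcript whose junction chain is a 3'-anchored suffix of another's (and
  whose 3' end matches) joins the group.  Every TSSC merge is also an ECC
  merge, so ECC never yields more models than TSSC.

Both modes assume the 3' end is intact (poly-A selected libraries); models
with unique termination sites are never collapsed.  Tolerances default to
exact matching; the 10/20-nt fuzz applies only to cross-library merging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .model import GeneModel, GenomicInterval, TranscriptModel


@dataclass
class CollapseGroup:
    representative: TranscriptModel
    members: Set[str]
    method: str  # "TSSC" or "ECC"


@dataclass
class MergeRecord:
    kept_id: str
    merged_ids: List[str]
    max_exon_shift: int
    max_end_shift: int


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {i: i for i in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra

    def groups(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for i in self.parent:
            out.setdefault(self.find(i), []).append(i)
        return out


def _pick_representative(members: Sequence[TranscriptModel]) -> TranscriptModel:
    """Longest spliced model; ties broken by lexicographically smaller id."""
    return sorted(members, key=lambda t: (-t.length, t.id))[0]


def _tts_match(a: TranscriptModel, b: TranscriptModel, end_tol: int) -> bool:
    return abs(a.tts - b.tts) <= end_tol


def _chains_equal(
    a: Tuple[Tuple[int, int], ...], b: Tuple[Tuple[int, int], ...], tol: int
) -> bool:
    if len(a) != len(b):
        return False
    return all(
        abs(x0 - y0) <= tol and abs(x1 - y1) <= tol for (x0, x1), (y0, y1) in zip(a, b)
    )


def _is_3prime_suffix(
    short: TranscriptModel, long: TranscriptModel, junction_tol: int
) -> bool:
    """True if *short*'s junction chain is a 3'-anchored suffix of *long*'s."""
    cs, cl = short.junctions, long.junctions
    if len(cs) > len(cl):
        return False
    if short.strand == "+":
        tail = cl[len(cl) - len(cs) :]
    else:  # 3' end is genomically left on the minus strand
        tail = cl[: len(cs)]
    return _chains_equal(cs, tail, junction_tol)


def _single_exon_tssc_pair(
    a: TranscriptModel, b: TranscriptModel, end_tol: int
) -> bool:
    """Single-exon transcripts group iff TTS matches and one contains the other."""
    if not _tts_match(a, b, end_tol):
        return False
    return a.span.contains(b.span) or b.span.contains(a.span)


def tssc_collapse(
    transcripts: Iterable[TranscriptModel],
    end_tol: int = 0,
    junction_tol: int = 0,
) -> List[CollapseGroup]:
    """Transcription start site collapse.

    Groups transcripts with identical junction chains (within
    ``junction_tol`` per junction coordinate) and identical TTS (within
    ``end_tol``); the representative is the longest member.  Single-exon
    transcripts group iff they share the TTS and one contains the other.
    Every input transcript appears in exactly one group (singletons
    included).
    """
    return _collapse(list(transcripts), end_tol, junction_tol, method="TSSC")


def ecc_collapse(
    transcripts: Iterable[TranscriptModel],
    end_tol: int = 0,
    junction_tol: int = 0,
) -> List[CollapseGroup]:
    """Exon cascade collapse: TSSC plus absorption of 5'-degraded models.

    A member joins a group when its junction chain is a (possibly complete)
    3'-anchored suffix of another member's and the TTS matches; a
    single-exon transcript collapses into a multi-exon transcript whose
    3'-terminal exon contains it with matching TTS.
    """
    return _collapse(list(transcripts), end_tol, junction_tol, method="ECC")


def _collapse(
    transcripts: List[TranscriptModel], end_tol: int, junction_tol: int, method: str
) -> List[CollapseGroup]:
    by_id = {t.id: t for t in transcripts}
    if len(by_id) != len(transcripts):
        raise ValueError("duplicate transcript ids in collapse input")
    uf = _UnionFind(by_id)

    # bucket by chrom/strand and (for exact tolerances) by TTS to keep the
    # pairwise comparison local
    buckets: Dict[Tuple, List[TranscriptModel]] = {}
    for t in transcripts:
        if end_tol == 0:
            key = (t.chrom, t.strand, t.tts)
        else:
            key = (t.chrom, t.strand)
        buckets.setdefault(key, []).append(t)

    for members in buckets.values():
        members = sorted(members, key=lambda t: (-len(t.junctions), -t.length, t.id))
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if not _tts_match(a, b, end_tol):
                    continue
                pair = False
                if a.n_exons > 1 and b.n_exons > 1:
                    if method == "TSSC":
                        pair = _chains_equal(a.junctions, b.junctions, junction_tol)
                    else:
                        pair = _is_3prime_suffix(b, a, junction_tol) or _is_3prime_suffix(
                            a, b, junction_tol
                        )
                elif a.n_exons == 1 and b.n_exons == 1:
                    pair = _single_exon_tssc_pair(a, b, end_tol)
                elif method == "ECC":
                    multi, single = (a, b) if a.n_exons > 1 else (b, a)
                    pair = multi.last_exon.contains(single.exons[0]) and _tts_match(
                        multi, single, end_tol
                    )
                if pair:
                    uf.union(a.id, b.id)

    groups = []
    for ids in uf.groups().values():
        members = [by_id[i] for i in ids]
        rep = _pick_representative(members)
        groups.append(CollapseGroup(rep, set(ids), method))
    groups.sort(key=lambda g: (g.representative.chrom, g.representative.span.start, g.representative.id))
    return groups


def collapse_loss_ratio(pre_count: int, post_count: int) -> float:
    """Percentage of transcript models removed by a collapse step."""
    if pre_count <= 0:
        raise ValueError("pre_count must be positive")
    if post_count > pre_count:
        raise ValueError("post_count cannot exceed pre_count")
    return 100.0 * (pre_count - post_count) / pre_count


# -- cross-library merging ----------------------------------------------


def _boundaries(t: TranscriptModel) -> List[int]:
    """Internal exon boundaries (every exon edge except the span ends)."""
    edges: List[int] = []
    for e in t.exons:
        edges.extend((e.start, e.end))
    return edges[1:-1]


def _mergeable(
    a: TranscriptModel, b: TranscriptModel, exon_tol: int, end_tol: int
) -> Optional[Tuple[int, int]]:
    if a.chrom != b.chrom or a.strand != b.strand or a.n_exons != b.n_exons:
        return None
    start_shift = abs(a.span.start - b.span.start)
    end_shift = abs(a.span.end - b.span.end)
    if start_shift >= end_tol or end_shift >= end_tol:
        return None
    max_exon_shift = 0
    for x, y in zip(_boundaries(a), _boundaries(b)):
        d = abs(x - y)
        if d >= exon_tol:
            return None
        max_exon_shift = max(max_exon_shift, d)
    return max_exon_shift, max(start_shift, end_shift)


def _earlier_start(a: TranscriptModel, b: TranscriptModel) -> TranscriptModel:
    """Transcript with the 5'-most (strand-aware) start; ties by smaller id."""
    if a.tss == b.tss:
        return a if a.id < b.id else b
    if a.strand == "+":
        return a if a.tss < b.tss else b
    return a if a.tss > b.tss else b


def merge_libraries(
    a: Iterable[TranscriptModel],
    b: Iterable[TranscriptModel],
    exon_tol: int = 10,
    end_tol: int = 20,
) -> Tuple[List[TranscriptModel], List[MergeRecord]]:
    """Merge two per-library transcript sets into one annotation.

    Transcripts merge iff they have the same exon count, every internal exon
    boundary differs by strictly less than ``exon_tol`` nt and both
    transcript ends differ by strictly less than ``end_tol`` nt (a 10-nt
    internal shift is NOT merged under the defaults).  The representative is
    the transcript with the earlier, strand-aware start.  Each transcript
    merges at most once, pairing greedily in deterministic genomic order.
    """
    a_list = sorted(a, key=lambda t: (t.chrom, t.span.start, t.id))
    b_list = sorted(b, key=lambda t: (t.chrom, t.span.start, t.id))
    b_index: Dict[Tuple[str, str, int], List[TranscriptModel]] = {}
    for t in b_list:
        b_index.setdefault((t.chrom, t.strand, t.n_exons), []).append(t)

    used_b: Set[str] = set()
    merged: List[TranscriptModel] = []
    records: List[MergeRecord] = []
    for t in a_list:
        partner = None
        shifts = None
        for cand in b_index.get((t.chrom, t.strand, t.n_exons), []):
            if cand.id in used_b:
                continue
            res = _mergeable(t, cand, exon_tol, end_tol)
            if res is not None:
                partner, shifts = cand, res
                break
        if partner is None:
            merged.append(t)
        else:
            used_b.add(partner.id)
            keep = _earlier_start(t, partner)
            other = partner if keep is t else t
            merged.append(keep)
            records.append(
                MergeRecord(
                    kept_id=keep.id,
                    merged_ids=[other.id],
                    max_exon_shift=shifts[0],
                    max_end_shift=shifts[1],
                )
            )
    merged.extend(t for t in b_list if t.id not in used_b)
    merged.sort(key=lambda t: (t.chrom, t.span.start, t.id))
    return merged, records


# -- gene clustering ------------------------------------------------------


def cluster_genes(transcripts: Iterable[TranscriptModel]) -> List[GeneModel]:
    """Cluster transcripts into genes by >=1-nt same-strand span overlap.

    Genes are the connected components of the overlap graph, computed with a
    sweep over sorted spans per (chrom, strand).  Opposite-strand overlaps do
    not join genes, so antisense partners remain distinct genes.  Gene ids
    are deterministic, ordered by (chrom, span start, strand).
    """
    by_cs: Dict[Tuple[str, str], List[TranscriptModel]] = {}
    for t in transcripts:
        by_cs.setdefault((t.chrom, t.strand), []).append(t)

    clusters: List[List[TranscriptModel]] = []
    for key in sorted(by_cs):
        members = sorted(by_cs[key], key=lambda t: (t.span.start, t.span.end, t.id))
        current: List[TranscriptModel] = []
        reach = -1
        for t in members:
            if current and t.span.start < reach:
                current.append(t)
                reach = max(reach, t.span.end)
            else:
                if current:
                    clusters.append(current)
                current = [t]
                reach = t.span.end
        if current:
            clusters.append(current)

    clusters.sort(key=lambda c: (c[0].chrom, min(t.span.start for t in c), c[0].strand))
    genes = []
    for i, members in enumerate(clusters, start=1):
        genes.append(
            GeneModel(
                id=f"gene{i:06d}",
                transcripts=tuple(sorted(members, key=lambda t: (t.span.start, t.id))),
            )
        )
    return genes


# -- unmapped read grouping ----------------------------------------------


def group_unmapped(
    hits: pd.DataFrame, reads: Optional[Iterable[str]] = None
) -> List[Set[str]]:
    """Group unmapped reads by same-strand pairwise hits.

    Groups are connected components over edges where both hit strands agree;
    self-hits are ignored and duplicate/inconsistent edges are treated as
    evidence, not constraints.  *reads* optionally supplies the full read
    universe so hit-less reads appear as singletons.
    """
    universe: Set[str] = set(reads) if reads is not None else set()
    universe.update(hits["read_a"])
    universe.update(hits["read_b"])
    uf = _UnionFind(sorted(universe))
    for row in hits.itertuples(index=False):
        if row.read_a == row.read_b:
            continue
        if row.strand_a == row.strand_b:
            uf.union(row.read_a, row.read_b)
    groups = [set(v) for v in uf.groups().values()]
    groups.sort(key=lambda g: sorted(g)[0])
    return groups


def coverage_efficiency(unique_transcripts: int, reads: int) -> float:
    """Unique transcripts per mapped read, as a percentage (one decimal)."""
    if reads <= 0:
        raise ValueError("reads must be positive")
    return round(100.0 * unique_transcripts / reads, 1)
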