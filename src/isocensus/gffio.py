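"""GFF3/GTF, FASTA and TSV input/output.

Reads exon features from GFF3 or GTF (attribute dialect auto-detected per
line via :mod:`gffutils`); writes canonical GFF3 only.  GFF3 coordinates are
1-based inclusive on disk and converted to the package-internal 0-based
half-open convention on read.
"""

from __future__ import annotations

import textwrap
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import pandas as pd
from gffutils.feature import feature_from_line

from .model import Annotation, GenomicInterval, TranscriptModel


class GffParseError(ValueError):
    pass


_TRANSCRIPT_KEYS = ("Parent", "transcript_id")
_GENE_KEYS = ("gene_id", "gene")


def _first(attrs, keys) -> Optional[str]:
    for k in keys:
        if k in attrs and attrs[k]:
            return attrs[k][0]
    return None


def read_gff3(path) -> Annotation:
    """Read exon features from a GFF3/GTF file into an :class:`Annotation`.

    Exons must carry a transcript identifier (``Parent`` in GFF3,
    ``transcript_id`` in GTF).  Transcript ids must be unique per file: the
    same id on two different chrom/strand placements is an error rather than
    being silently suffixed.  Gene grouping honours an explicit ``gene_id``
    attribute when present on every exon, otherwise genes are rebuilt by
    same-strand overlap clustering.
    """
    path = Path(path)
    exon_rows: Dict[str, List] = {}
    meta: Dict[str, Dict[str, str]] = {}
    gene_tags: Dict[str, Optional[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") < 7:
                raise GffParseError(f"{path}:{lineno}: malformed feature line")
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # pragma: no cover - gffutils detail
                raise GffParseError(f"{path}:{lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            tid = _first(feat.attributes, _TRANSCRIPT_KEYS)
            if tid is None:
                raise GffParseError(
                    f"{path}:{lineno}: exon without Parent/transcript_id"
                )
            if feat.strand not in ("+", "-"):
                raise GffParseError(f"{path}:{lineno}: exon without strand")
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            exon_rows.setdefault(tid, []).append(iv)
            tags = {
                k: feat.attributes[k][0]
                for k in feat.attributes.keys()
                if k not in ("Parent", "ID", "transcript_id", "gene_id", "gene")
            }
            meta.setdefault(tid, {}).update(tags)
            gene_tags.setdefault(tid, _first(feat.attributes, _GENE_KEYS))

    transcripts = []
    for tid, exons in exon_rows.items():
        tags = meta.get(tid, {})
        transcripts.append(
            TranscriptModel(
                id=tid,
                exons=tuple(exons),
                source_library=tags.pop("source_library", ""),
                cap_selected=tags.pop("cap_selected", "0") in ("1", "true", "True"),
                attributes=tags,
            )
        )

    gene_ids = [gene_tags.get(t.id) for t in transcripts]
    if transcripts and all(g is not None for g in gene_ids):
        from .model import GeneModel

        by_gene: Dict[str, List[TranscriptModel]] = {}
        for t, g in zip(transcripts, gene_ids):
            by_gene.setdefault(g, []).append(t)
        genes = [
            GeneModel(id=g, transcripts=tuple(sorted(ts, key=lambda t: (t.span.start, t.id))))
            for g, ts in by_gene.items()
        ]
        genes.sort(key=lambda g: (g.chrom, g.span.start, g.id))
        return Annotation(genes)
    return Annotation.from_transcripts(transcripts)


def write_gff3(annotation: Annotation, path) -> None:
    """Write an annotation as GFF3 (exon features, deterministic ordering).

    Output is ordered by (chrom, gene start, gene id, transcript start,
    transcript id); repeated writes of the same annotation are byte-identical.
    Transcript-level tags (source library, cap selection, biotype and event
    flags) are emitted on every exon row.
    """
    lines = ["##gff-version 3"]
    genes = sorted(annotation.genes, key=lambda g: (g.chrom, g.span.start, g.id))
    for g in genes:
        for t in sorted(g.transcripts, key=lambda t: (t.span.start, t.id)):
            tags = [f"Parent={t.id}", f"gene_id={g.id}"]
            if t.source_library:
                tags.append(f"source_library={t.source_library}")
            if t.cap_selected:
                tags.append("cap_selected=1")
            for k in sorted(t.attributes):
                tags.append(f"{k}={t.attributes[k]}")
            for i, e in enumerate(t.exons, start=1):
                attrs = ";".join([f"ID={t.id}.exon{i}"] + tags)
                lines.append(
                    "\t".join(
                        [
                            e.chrom,
                            "isocensus",
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            e.strand,
                            ".",
                            attrs,
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


# -- FASTA ---------------------------------------------------------------


def write_fasta(records: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(records[name], width)) + "\n")


def read_fasta(path) -> Dict[str, str]:
    records: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    return records


# -- TSV tables ----------------------------------------------------------


def read_evidence(path) -> pd.DataFrame:
    """Read the per-transcript coding-evidence table.

    Columns: ``transcript_id``, ``has_protein_hit`` (0/1), ``cpc_label``
    (coding/noncoding/NA), ``cpat_score`` ([0,1] or NA) and optionally
    ``orf_hit_end`` / ``orf_hit_score`` identifying which open reading frame
    (by the transcript coordinate of its stop) carries a protein hit.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    if "transcript_id" not in df.columns:
        raise ValueError("evidence table needs a transcript_id column")
    return df


def read_hits(path) -> pd.DataFrame:
    """Read a pairwise same/opposite-strand hit table for unmapped reads."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"read_a", "read_b", "strand_a", "strand_b"}
    if not required.issubset(df.columns):
        raise ValueError(f"hit table needs columns {sorted(required)}")
    return df
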