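"""Seeded simulator: genome, ground-truth annotation and noisy reads.

The generator builds a small random genome and plants gene units whose
isoform structures realize each alternative-transcription event *by
construction*: alternative start/termination exons get their own splice
boundaries, retained-intron and skipped-exon isoforms are derived from a
base model, and alternative exon starts/ends shift one boundary of an
internal exon.  Coding genes carry a frame-consistent CDS across all
isoforms (internal exon lengths and all structural shifts are multiples of
three, and downstream exon boundaries are codon-aligned), so spliced
variants of a coding gene never acquire accidental premature stops; NMD
isoforms gain a "poison" cassette exon carrying an in-frame stop more than
50 nt upstream of the final junction.  Internal poly-A runs, GT-AG (or
non-canonical GC-AG) splice dinucleotides and antisense/sense-overlapping
lncRNA partners are planted per configured rates, and every planted label
is recorded as ground truth for recovery tests.

Observed reads are copies of the truth transcripts with optional 5'
degradation (dropped 5' exons), substitution/indel sequence errors and
appended poly-A tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .model import (
    Annotation,
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
    spliced_sequence,
)

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
)
# CDS interiors avoid in-frame ATG as well as stops, so the planted start
# codon is the only in-frame initiation site and truncated isoforms cannot
# spawn long in-frame competitor ORFs downstream of a premature stop
CDS_CODONS = tuple(c for c in SENSE_CODONS if c != "ATG")

# structural offsets (all multiples of 3 where they touch coding sequence)
TSS_WOBBLE = 60
TTS_STEP = 60
JUNCTION_SHIFT = 15
POLYA_RUN = 24


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Default rates mirror the qualitative regime of a two-tissue long-read
    survey of a vertebrate transcriptome: roughly half of the gene units
    are protein coding, lncRNA are predominantly single-exon, and
    multi-transcript genes are dominated by alternative TSS/TTS usage, with
    retained introns and skipped exons at intermediate rates and
    alternative internal exon boundaries rare.
    """

    seed: int = 1
    n_chroms: int = 2
    n_genes: int = 60
    # gene-unit biotype mix
    p_coding: float = 0.55
    p_lincrna: float = 0.41
    p_short_ncrna: float = 0.04
    # isoform-count regime
    p_mt_coding: float = 0.54
    p_mt_lnc: float = 0.12
    p_coding_single_exon: float = 0.12
    p_lnc_single_exon: float = 0.70
    # event rates among multi-transcript coding genes
    p_multi_tss: float = 0.95
    p_multi_tse_given_tss: float = 0.73
    p_multi_tts: float = 0.92
    p_multi_tte_given_tts: float = 0.83
    p_retained_intron: float = 0.35
    p_skipped_exon: float = 0.50
    p_aes: float = 0.19
    p_aee: float = 0.20
    nmd_isoform_rate: float = 0.20
    # lncRNA partner / overlap rates (attached to eligible gene units)
    p_antisense_lnc_partner: float = 0.08
    p_antisense_coding_partner: float = 0.03
    p_intronic_antisense_partner: float = 0.04
    p_sense_exonic_lnc: float = 0.06
    p_sense_intronic_lnc: float = 0.04
    p_lnc_antisense_pair: float = 0.04
    # sequence-level planting
    fraction_canonical: float = 0.97
    internal_polyA_rate: float = 0.02
    # libraries
    p_embryo: float = 0.35
    p_both_libraries: float = 0.05
    # observed-read generation
    copies_per_transcript: int = 1
    degradation_rate: float = 0.0
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    corrupt_fraction: float = 0.0
    corrupt_sub_rate: float = 0.12
    polyA_tail_mean: float = 0.0  # 0 disables tail appending
    # layout
    intergenic_gap: Tuple[int, int] = (150, 300)

    def validate(self) -> None:
        probs = [
            v
            for k, v in self.__dict__.items()
            if k.startswith("p_") or k.endswith("_rate") or k == "fraction_canonical"
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all rates must lie in [0, 1]")
        if abs(self.p_coding + self.p_lincrna + self.p_short_ncrna - 1.0) > 1e-9:
            raise ValueError("gene-unit biotype mix must sum to 1")
        if self.copies_per_transcript < 1:
            raise ValueError("copies_per_transcript must be >= 1")


@dataclass
class TruthTranscript:
    id: str
    gene_key: str
    exons: Tuple[Tuple[int, int], ...]  # genomic, 0-based half-open
    chrom: str
    strand: str
    biotype: str  # coding / NMD / lncRNA / short_ncRNA
    lnc_class: Optional[str]
    library: str
    cap_selected: bool
    both_libraries: bool
    canonical: Optional[bool]  # None for single-exon
    polyA_planted: bool
    cds_start_t: Optional[int]  # transcript coords of ATG
    stop_end_t: Optional[int]  # transcript coords just past the stop codon


@dataclass
class SyntheticTruth:
    config: SimConfig
    transcripts: Dict[str, TruthTranscript]
    gene_flags: Dict[str, Dict[str, bool]]  # unit key -> event flags
    gene_key_of: Dict[str, str]

    def annotation(self) -> Annotation:
        models = [
            TranscriptModel(
                id=t.id,
                exons=tuple(
                    GenomicInterval(t.chrom, s, e, t.strand) for s, e in t.exons
                ),
                source_library=t.library,
                cap_selected=t.cap_selected,
            )
            for t in self.transcripts.values()
        ]
        return Annotation.from_transcripts(models)

    def evidence_frame(
        self, ids_with_parent: Iterable[Tuple[str, str]], rng: np.random.Generator
    ) -> pd.DataFrame:
        """External coding-evidence table consistent with the planted truth.

        Coding and NMD transcripts receive positive evidence from at least
        one of the three sources plus a protein hit on the planted ORF
        (identified by its stop's transcript coordinate); noncoding
        transcripts receive uniformly sub-threshold CPAT scores and
        noncoding/missing CPC labels.
        """
        rows = []
        for rid, parent in ids_with_parent:
            t = self.transcripts[parent]
            if t.biotype in ("coding", "NMD"):
                hit = rng.random() < 0.9
                cpc = "coding" if rng.random() < 0.85 else "noncoding"
                cpat = round(float(rng.uniform(0.3, 0.99)), 3)
                rows.append(
                    {
                        "transcript_id": rid,
                        "has_protein_hit": int(hit),
                        "cpc_label": cpc,
                        "cpat_score": cpat,
                        "orf_hit_end": t.stop_end_t,
                        "orf_hit_score": round(float(rng.uniform(60, 300)), 1),
                    }
                )
            else:
                cpc = "noncoding" if rng.random() < 0.9 else "NA"
                cpat = (
                    round(float(rng.uniform(0.0, 0.295)), 3)
                    if rng.random() < 0.8
                    else None
                )
                rows.append(
                    {
                        "transcript_id": rid,
                        "has_protein_hit": 0,
                        "cpc_label": cpc,
                        "cpat_score": cpat,
                        "orf_hit_end": None,
                        "orf_hit_score": None,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "transcript_id",
                "has_protein_hit",
                "cpc_label",
                "cpat_score",
                "orf_hit_end",
                "orf_hit_score",
            ],
        )


# ---------------------------------------------------------------------
# gene-unit construction (all positions unit-relative, in *sense*
# orientation: position 0 is 5'-most; the whole unit is reverse
# complemented at genome placement for minus-strand genes)
# ---------------------------------------------------------------------


@dataclass
class _Isoform:
    name: str
    exons: List[Tuple[int, int]]
    biotype: str = "coding"
    lnc_class: Optional[str] = None
    opposite_strand: bool = False
    atg: Optional[int] = None  # unit-relative sense position of ATG
    stop: Optional[int] = None  # unit-relative sense position of stop codon start
    own_content: Optional[str] = None  # for opposite-strand coding partners


@dataclass
class _Unit:
    key: str
    isoforms: List[_Isoform] = field(default_factory=list)
    flags: Dict[str, bool] = field(default_factory=dict)
    width: int = 0


def _mult3(rng: np.random.Generator, lo: int, hi: int) -> int:
    return 3 * int(rng.integers(lo // 3, hi // 3 + 1))


def _layout(rng, k, first=(150, 220), internal=(120, 240), last=(90, 150),
            introns=(141, 219), enlarged_last_intron: Optional[int] = None):
    """Exon/intron layout in sense coordinates starting at 10."""
    exon_lens = []
    for i in range(k):
        if i == 0:
            exon_lens.append(int(rng.integers(first[0], first[1] + 1)))
        elif i == k - 1:
            exon_lens.append(_mult3(rng, last[0], last[1]))
        else:
            exon_lens.append(_mult3(rng, internal[0], internal[1]))
    intron_lens = [_mult3(rng, introns[0], introns[1]) for _ in range(k - 1)]
    if enlarged_last_intron and k >= 2:
        intron_lens[-1] = enlarged_last_intron
    exons = []
    cursor = 10
    for i in range(k):
        exons.append((cursor, cursor + exon_lens[i]))
        cursor += exon_lens[i]
        if i < k - 1:
            cursor += intron_lens[i]
    return exons


def _build_coding_unit(rng: np.random.Generator, cfg: SimConfig, key: str) -> _Unit:
    unit = _Unit(key=key)
    flags = {n: False for n in (
        "multi_TSS", "multi_TSE", "multi_TTS", "multi_TTE",
        "retained_intron", "skipped_exon", "AES", "AEE",
    )}

    mt = rng.random() < cfg.p_mt_coding
    single_exon = (not mt) and rng.random() < cfg.p_coding_single_exon

    # attachments (mutually exclusive with an NMD isoform, and with each
    # other where they would share the same intron)
    sense_exonic = rng.random() < cfg.p_sense_exonic_lnc
    sense_intronic = (not sense_exonic) and rng.random() < cfg.p_sense_intronic_lnc
    anti_exonic = rng.random() < (
        cfg.p_antisense_lnc_partner + cfg.p_antisense_coding_partner
    )
    anti_coding = anti_exonic and rng.random() < (
        cfg.p_antisense_coding_partner
        / max(cfg.p_antisense_lnc_partner + cfg.p_antisense_coding_partner, 1e-12)
    )
    anti_intronic = (not sense_intronic) and rng.random() < cfg.p_intronic_antisense_partner
    needs_intron_overlap = sense_intronic or anti_intronic
    if needs_intron_overlap or sense_exonic:
        single_exon = False
    min_exons = 4 if (needs_intron_overlap or sense_exonic) else 2

    if single_exon:
        length = _mult3(rng, 402, 702)
        exons = [(10, 10 + length)]
        atg = 10 + 30
        cds_len = 3 * ((length - 120) // 3)
        stop = atg + cds_len - 3
        unit.isoforms.append(_Isoform("t1", exons, atg=atg, stop=stop))
        unit.flags = flags
        unit.width = exons[-1][1] + 40
        return unit

    # sample events (only meaningful for multi-transcript genes)
    ev = {}
    if mt:
        ev["tss"] = rng.random() < cfg.p_multi_tss
        ev["tse"] = ev["tss"] and rng.random() < cfg.p_multi_tse_given_tss
        ev["tts"] = rng.random() < cfg.p_multi_tts
        ev["tte"] = ev["tts"] and rng.random() < cfg.p_multi_tte_given_tts
        ev["retained"] = rng.random() < cfg.p_retained_intron
        ev["skip"] = rng.random() < cfg.p_skipped_exon
        ev["aes"] = rng.random() < cfg.p_aes
        ev["aee"] = rng.random() < cfg.p_aee
        ev["nmd"] = (
            rng.random() < cfg.nmd_isoform_rate
            and not (sense_exonic or sense_intronic or anti_intronic)
        )
    else:
        ev = {k: False for k in ("tss", "tse", "tts", "tte", "retained",
                                 "skip", "aes", "aee", "nmd")}

    # exon count: multi-transcript event genes need room for internal edits
    if mt:
        k = int(rng.integers(4, 8))
        if ev["nmd"] and ev["retained"]:
            k = max(k, 5)
    else:
        k = int(rng.integers(2, 7))
    k = max(k, min_exons)

    utr3 = _mult3(rng, 66, 117)
    if anti_exonic:
        utr3 = _mult3(rng, 252, 300)
    if k == 2:
        # CDS confined to the terminal exon, which must hold it plus the UTR
        last = (9 + 240 + 3 + utr3, 9 + 360 + 3 + utr3)
    else:
        last = (21 + 3 + utr3, 21 + 3 + utr3)
    enlarged = 330 if needs_intron_overlap else None
    exons = _layout(rng, k, last=last, enlarged_last_intron=enlarged)

    atg = exons[1][0] + 9
    stop = exons[-1][0] + 21
    if k == 2:
        l2 = exons[1][1] - exons[1][0]
        cds_len = 3 * ((l2 - 9 - utr3 - 3) // 3)
        stop = atg + cds_len

    base = _Isoform("t1", list(exons), atg=atg, stop=stop)
    isoforms = [base]

    def add(name: str, new_exons: List[Tuple[int, int]], stop_pos: int = None):
        isoforms.append(
            _Isoform(name, new_exons, atg=atg, stop=stop if stop_pos is None else stop_pos)
        )

    n = 1
    if ev["tse"]:
        n += 1
        g = (exons[0][0] + 30, exons[0][1] + JUNCTION_SHIFT)
        add(f"t{n}", [g] + list(exons[1:]))
        flags["multi_TSE"] = True
        flags["multi_TSS"] = True
    elif ev["tss"]:
        n += 1
        w = (exons[0][0] + TSS_WOBBLE, exons[0][1])
        add(f"t{n}", [w] + list(exons[1:]))
        flags["multi_TSS"] = True
        ev["tts"] = True  # a pure-TSS variant needs its own 3' end
    if ev["tte"]:
        n += 1
        f = (exons[-1][0] + JUNCTION_SHIFT, exons[-1][1])
        add(f"t{n}", list(exons[:-1]) + [f])
        flags["multi_TTE"] = True
        flags["multi_TTS"] = True
    if ev["retained"]:
        n += 1
        # never the first intron (a retained first intron is indistinguishable
        # from 5' degradation under the cascade collapse), never the last
        # (reserved for intron overlaps), and never the poison-exon intron
        allowed = [i for i in range(1, k - 2) if not (ev["nmd"] and i == 2)]
        i = allowed[int(rng.integers(len(allowed)))]
        merged = (exons[i][0], exons[i + 1][1])
        add(f"t{n}", list(exons[:i]) + [merged] + list(exons[i + 2:]))
        flags["retained_intron"] = True
    if ev["skip"]:
        n += 1
        # never skip the ATG-bearing second exon
        j = int(rng.integers(2, k - 1))
        add(f"t{n}", list(exons[:j]) + list(exons[j + 1:]))
        flags["skipped_exon"] = True
    if ev["aes"]:
        n += 1
        # a 5'-boundary shift of exon 2 would cut off the ATG
        m = int(rng.integers(2, k - 1))
        e = exons[m]
        add(f"t{n}", list(exons[:m]) + [(e[0] + JUNCTION_SHIFT, e[1])] + list(exons[m + 1:]))
        flags["AES"] = True
    if ev["aee"]:
        n += 1
        m = int(rng.integers(1, k - 1))
        e = exons[m]
        add(f"t{n}", list(exons[:m]) + [(e[0], e[1] - JUNCTION_SHIFT)] + list(exons[m + 1:]))
        flags["AEE"] = True
    if ev["nmd"]:
        n += 1
        # poison cassette exon in the intron after exon 3, deep enough that
        # the premature-stop ORF is a substantial fraction of the CDS
        intron_s = exons[2][1]
        p = (intron_s + 18, intron_s + 18 + 90)
        nmd_exons = list(exons[:3]) + [p] + list(exons[3:])
        nmd_stop = p[0] + 6
        isoforms.append(
            _Isoform(f"t{n}", nmd_exons, biotype="NMD", atg=atg, stop=nmd_stop)
        )
        flags["skipped_exon"] = True  # a cassette exon sits in the base intron

    if mt and len(isoforms) == 1:
        # gene drew no structural event: realize multiplicity as a 3'-end shift
        n += 1
        add(f"t{n}", list(exons))
        ev["tts"] = True

    if ev["tts"]:
        flags["multi_TTS"] = True
        for rank, iso in enumerate(isoforms):
            s, e = iso.exons[-1]
            iso.exons[-1] = (s, e + TTS_STEP * rank)
    if ev["tte"]:
        flags["multi_TTS"] = True

    # sense-overlapping lncRNA transcripts join the host gene
    if sense_exonic:
        e2 = base.exons[1]
        iso = _Isoform(
            "se_lnc", [(e2[0] + 12, e2[0] + 252)], biotype="lncRNA",
            lnc_class="sense_exonic",
        )
        isoforms.append(iso)
        for name in ("multi_TSS", "multi_TSE", "multi_TTS", "multi_TTE"):
            flags[name] = True
    if sense_intronic:
        intron_s, intron_e = base.exons[-2][1], base.exons[-1][0]
        iso = _Isoform(
            "si_lnc", [(intron_s + 24, intron_s + 24 + 252)], biotype="lncRNA",
            lnc_class="sense_intronic",
        )
        isoforms.append(iso)
        for name in ("multi_TSS", "multi_TSE", "multi_TTS", "multi_TTE",
                     "skipped_exon"):
            flags[name] = True

    unit.isoforms = isoforms
    unit.flags = flags

    # opposite-strand partners (their own genes)
    if anti_exonic:
        a0 = stop + 9
        interval = (a0, a0 + 231)
        if anti_coding:
            content = _partner_coding_content(rng, 231)
            unit.isoforms.append(
                _Isoform(
                    "as_cod", [interval], biotype="coding", opposite_strand=True,
                    atg=9, stop=219, own_content=content,
                )
            )
        else:
            unit.isoforms.append(
                _Isoform(
                    "as_lnc", [interval], biotype="lncRNA", lnc_class="antisense",
                    opposite_strand=True,
                )
            )
    if anti_intronic:
        intron_s = base.exons[-2][1]
        unit.isoforms.append(
            _Isoform(
                "ai_lnc", [(intron_s + 24, intron_s + 24 + 252)],
                biotype="lncRNA", lnc_class="lincRNA", opposite_strand=True,
            )
        )

    unit.width = max(e for iso in unit.isoforms for _, e in iso.exons) + 40
    return unit


def _partner_coding_content(rng: np.random.Generator, length: int) -> str:
    """Sense content for a single-exon coding partner: ATG..stop, stop-free CDS."""
    seq = list(rng.choice(BASES, size=length))
    seq[9:12] = "ATG"
    pos = 12
    while pos + 3 <= 219:
        seq[pos : pos + 3] = CDS_CODONS[int(rng.integers(len(CDS_CODONS)))]
        pos += 3
    seq[219:222] = STOPS[int(rng.integers(3))]
    return "".join(seq)


def _build_lnc_unit(rng: np.random.Generator, cfg: SimConfig, key: str) -> _Unit:
    unit = _Unit(key=key)
    flags = {n: False for n in (
        "multi_TSS", "multi_TSE", "multi_TTS", "multi_TTE",
        "retained_intron", "skipped_exon", "AES", "AEE",
    )}
    single = rng.random() < cfg.p_lnc_single_exon
    mt = rng.random() < cfg.p_mt_lnc
    if single:
        length = int(rng.integers(240, 421))
        exons = [(10, 10 + length)]
    else:
        k = int(rng.integers(2, 5))
        exons = _layout(rng, k, first=(120, 200), internal=(120, 240),
                        last=(120, 210), introns=(141, 201))
    isoforms = [_Isoform("t1", list(exons), biotype="lncRNA", lnc_class="lincRNA")]
    if mt:
        second = [list(e) for e in exons]
        s, e = second[-1]
        second[-1] = (s, e + TTS_STEP)
        isoforms.append(
            _Isoform("t2", [tuple(x) for x in second], biotype="lncRNA",
                     lnc_class="lincRNA")
        )
        flags["multi_TTS"] = True
    if rng.random() < cfg.p_lnc_antisense_pair:
        e1 = exons[0]
        start = e1[0] + 15
        end = min(start + 222, e1[1] + 117)  # never reaches a second exon
        if end - start >= 200:
            isoforms.append(
                _Isoform("as_lnc", [(start, end)], biotype="lncRNA",
                         lnc_class="lincRNA", opposite_strand=True)
            )
    unit.isoforms = isoforms
    unit.flags = flags
    unit.width = max(e for iso in unit.isoforms for _, e in iso.exons) + 40
    return unit


def _build_short_nc_unit(rng: np.random.Generator, cfg: SimConfig, key: str) -> _Unit:
    unit = _Unit(key=key)
    length = int(rng.integers(120, 181))
    unit.isoforms = [_Isoform("t1", [(10, 10 + length)], biotype="short_ncRNA")]
    unit.flags = {n: False for n in (
        "multi_TSS", "multi_TSE", "multi_TTS", "multi_TTE",
        "retained_intron", "skipped_exon", "AES", "AEE",
    )}
    unit.width = 10 + length + 40
    return unit


# ---------------------------------------------------------------------
# sequence planting
# ---------------------------------------------------------------------


def _plant_unit_sequence(
    rng: np.random.Generator, cfg: SimConfig, unit: _Unit
) -> Tuple[np.ndarray, Dict[int, bool], Set[int]]:
    """Fill the unit's sense-orientation sequence.

    Returns (sequence array, donor_position -> canonical flag,
    set of TTS sites carrying a planted poly-A run).
    """
    seq = rng.choice(BASES, size=unit.width)
    fixed: Set[int] = set()

    def write(pos: int, s: str) -> None:
        for i, b in enumerate(s):
            seq[pos + i] = b
            fixed.add(pos + i)

    # 1. splice dinucleotides (canonical draw per unique donor)
    donors: Dict[int, bool] = {}
    acceptors: Set[int] = set()
    for iso in unit.isoforms:
        if iso.opposite_strand:
            continue
        for (s0, e0), (s1, e1) in zip(iso.exons, iso.exons[1:]):
            if e0 not in donors:
                donors[e0] = bool(rng.random() < cfg.fraction_canonical)
            acceptors.add(s1)
    for d, canon in sorted(donors.items()):
        write(d, "GT" if canon else "GC")
    for a in sorted(acceptors):
        write(a - 2, "AG")

    # 2. planted start/stop codons
    planted_codons: Set[Tuple[int, int]] = set()
    for iso in unit.isoforms:
        if iso.opposite_strand or iso.atg is None:
            continue
        planted_codons.add((iso.atg, 0))
        planted_codons.add((iso.stop, 1))
    for pos, kind in sorted(planted_codons):
        write(pos, "ATG" if kind == 0 else STOPS[int(rng.integers(3))])

    # 3. frame-consistent CDS codons on every exonic (or variant-read)
    #    coding region
    def fill_codons(regions: List[Tuple[int, int]]) -> None:
        """Fill codon-aligned regions with non-stop codons, honouring fixed bases."""
        for s0, e0 in regions:
            pos = s0
            while pos + 3 <= e0:
                codon = tuple(range(pos, pos + 3))
                if all(p in fixed for p in codon):
                    pos += 3
                    continue
                constraint = {
                    i: str(seq[pos + i]) for i in range(3) if (pos + i) in fixed
                }
                choices = [
                    c
                    for c in CDS_CODONS
                    if all(c[i] == b for i, b in constraint.items())
                ]
                c = choices[int(rng.integers(len(choices)))]
                for i in range(3):
                    if pos + i not in fixed:
                        seq[pos + i] = c[i]
                pos += 3

    for iso in unit.isoforms:
        if iso.opposite_strand or iso.atg is None:
            continue
        regions = []
        for s0, e0 in iso.exons:
            lo, hi = max(s0, iso.atg), min(e0, iso.stop)
            if lo < hi:
                regions.append((lo, hi))
        fill_codons(regions)
    # mark CDS regions fixed after filling so overlapping isoforms agree
    for iso in unit.isoforms:
        if iso.opposite_strand or iso.atg is None:
            continue
        for s0, e0 in iso.exons:
            lo, hi = max(s0, iso.atg), min(e0, iso.stop + 3)
            fixed.update(range(lo, hi))

    # 4. opposite-strand partner content (written as its reverse complement)
    for iso in unit.isoforms:
        if iso.opposite_strand and iso.own_content is not None:
            s0, e0 = iso.exons[0]
            rc = reverse_complement(iso.own_content)
            for i, b in enumerate(rc):
                seq[s0 + i] = b
                fixed.add(s0 + i)

    # 5. internal poly-A runs per distinct TTS site
    sense_tts_sites = sorted(
        {iso.exons[-1][1] for iso in unit.isoforms if not iso.opposite_strand}
    )
    polyA_sites: Set[int] = set()
    for site in sense_tts_sites:
        if rng.random() < cfg.internal_polyA_rate:
            write(site, "A" * POLYA_RUN)
            polyA_sites.add(site)
    return seq, donors, polyA_sites


# ---------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------


def generate(cfg: SimConfig) -> Tuple[Dict[str, str], SyntheticTruth]:
    """Generate (genome, truth) for the configured study conditions."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chrom_seqs: Dict[str, List[str]] = {
        f"chr{i + 1}": [] for i in range(cfg.n_chroms)
    }
    cursors = {c: 0 for c in chrom_seqs}

    transcripts: Dict[str, TruthTranscript] = {}
    gene_flags: Dict[str, Dict[str, bool]] = {}
    gene_key_of: Dict[str, str] = {}

    for gi in range(cfg.n_genes):
        key = f"g{gi + 1:05d}"
        u = rng.random()
        if u < cfg.p_coding:
            unit = _build_coding_unit(rng, cfg, key)
        elif u < cfg.p_coding + cfg.p_lincrna:
            unit = _build_lnc_unit(rng, cfg, key)
        else:
            unit = _build_short_nc_unit(rng, cfg, key)

        seq, donors, polyA_sites = _plant_unit_sequence(rng, cfg, unit)
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = f"chr{(gi % cfg.n_chroms) + 1}"
        gap = int(rng.integers(*cfg.intergenic_gap))
        filler = "".join(rng.choice(BASES, size=gap))
        offset = cursors[chrom] + gap

        unit_seq = "".join(seq)
        if strand == "-":
            unit_seq = reverse_complement(unit_seq)
        chrom_seqs[chrom].append(filler)
        chrom_seqs[chrom].append(unit_seq)
        cursors[chrom] = offset + unit.width

        W = unit.width

        def to_genomic(interval: Tuple[int, int]) -> Tuple[int, int]:
            s, e = interval
            if strand == "+":
                return offset + s, offset + e
            return offset + W - e, offset + W - s

        gene_flags[key] = dict(unit.flags)
        for iso in unit.isoforms:
            tid = f"{key}.{iso.name}"
            iso_strand = strand
            if iso.opposite_strand:
                iso_strand = "-" if strand == "+" else "+"
            g_exons = tuple(sorted(to_genomic(e) for e in iso.exons))
            library = "embryo" if rng.random() < cfg.p_embryo else "brain"
            both = rng.random() < cfg.p_both_libraries
            # transcript-coordinate CDS landmarks (sense space == transcript space)
            cds_start_t = stop_end_t = None
            if iso.atg is not None:
                if iso.own_content is not None:
                    cds_start_t, stop_end_t = iso.atg, iso.stop + 3
                else:
                    cds_start_t = _sense_to_transcript(iso.exons, iso.atg)
                    stop_end_t = _sense_to_transcript(iso.exons, iso.stop + 2) + 1
            if iso.opposite_strand:
                gkey = f"{key}.{iso.name}"
                gene_flags[gkey] = {n: False for n in unit.flags}
            else:
                gkey = key
            canonical: Optional[bool] = None
            if not iso.opposite_strand and len(iso.exons) > 1:
                canonical = all(donors[e] for (_, e) in iso.exons[:-1])
            elif iso.opposite_strand and len(iso.exons) > 1:
                canonical = True
            polyA = (not iso.opposite_strand) and iso.exons[-1][1] in polyA_sites
            biotype = iso.biotype
            tt = TruthTranscript(
                id=tid,
                gene_key=gkey,
                exons=g_exons,
                chrom=chrom,
                strand=iso_strand,
                biotype=biotype,
                lnc_class=iso.lnc_class,
                library=library,
                cap_selected=(library == "embryo") or both,
                both_libraries=both,
                canonical=canonical,
                polyA_planted=polyA,
                cds_start_t=cds_start_t,
                stop_end_t=stop_end_t,
            )
            transcripts[tid] = tt
            gene_key_of[tid] = gkey

    genome = {c: "".join(parts) for c, parts in chrom_seqs.items()}
    # pad chromosome ends so downstream windows stay in bounds
    pad_rng = np.random.default_rng(cfg.seed + 10_007)
    genome = {c: s + "".join(pad_rng.choice(BASES, size=60)) for c, s in genome.items()}
    return genome, SyntheticTruth(cfg, transcripts, gene_flags, gene_key_of)


def _sense_to_transcript(exons: Sequence[Tuple[int, int]], pos: int) -> int:
    """Map a unit-sense position inside an exon to transcript coordinates."""
    acc = 0
    for s, e in exons:
        if s <= pos < e:
            return acc + (pos - s)
        acc += e - s
    raise ValueError(f"position {pos} not exonic")


# ---------------------------------------------------------------------
# observed reads
# ---------------------------------------------------------------------


@dataclass
class ObservedRead:
    model: TranscriptModel
    parent: str
    degraded: bool
    clean_seq: str  # genome-projected sequence (no errors, no tail)
    corrupted: bool = False  # drawn from the elevated error-rate fraction


def degrade_and_corrupt(
    genome: Dict[str, str], truth: SyntheticTruth, cfg: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[ObservedRead]:
    """Emit per-transcript read copies with optional 5' degradation and errors.

    Copy 0 of every transcript is always intact; additional copies (when
    ``copies_per_transcript`` > 1) independently lose one or more 5' exons
    with probability ``degradation_rate``.  Cap-selected copies are exempt
    from degradation.  Sequence errors (substitutions/indels) are applied
    per read at the configured rates, with a ``corrupt_fraction`` of reads
    drawn at the elevated ``corrupt_sub_rate``; a poly-A tail of geometric
    length is appended when ``polyA_tail_mean`` > 0.
    """
    cfg = cfg or truth.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 20_011)
    reads: List[ObservedRead] = []
    for tid in sorted(truth.transcripts):
        t = truth.transcripts[tid]
        libraries = [t.library]
        if t.both_libraries:
            libraries = ["brain", "embryo"]
        for lib in libraries:
            cap = lib == "embryo"
            for copy in range(cfg.copies_per_transcript):
                exons = list(t.exons)
                degraded = False
                if (
                    copy > 0
                    and not cap
                    and rng.random() < cfg.degradation_rate
                ):
                    degraded = True
                    if len(exons) > 1:
                        drop = int(rng.integers(1, len(exons)))
                        if t.strand == "+":
                            exons = exons[drop:]
                        else:
                            exons = exons[:-drop]
                    else:
                        s, e = exons[0]
                        cut = int((e - s) * rng.uniform(0.3, 0.5))
                        exons = [(s + cut, e) if t.strand == "+" else (s, e - cut)]
                model = TranscriptModel(
                    id=f"{tid}|{lib}|r{copy}",
                    exons=tuple(
                        GenomicInterval(t.chrom, s, e, t.strand) for s, e in exons
                    ),
                    source_library=lib,
                    cap_selected=cap,
                )
                clean = spliced_sequence(genome, model)
                noisy, corrupted = _apply_errors(rng, cfg, clean)
                if cfg.polyA_tail_mean > 0:
                    tail = int(rng.geometric(1.0 / cfg.polyA_tail_mean))
                    noisy = noisy + "A" * tail
                model.sequence = noisy
                reads.append(ObservedRead(model, tid, degraded, clean, corrupted))
    return reads


def _apply_errors(
    rng: np.random.Generator, cfg: SimConfig, seq: str
) -> Tuple[str, bool]:
    sub = cfg.sub_rate
    corrupted = False
    if cfg.corrupt_fraction > 0 and rng.random() < cfg.corrupt_fraction:
        corrupted = True
        # plant exactly rate*length substitutions so the realized error rate
        # of a corrupted read matches the configured rate, not a binomial draw
        n_sub = int(round(cfg.corrupt_sub_rate * len(seq)))
        positions = rng.choice(len(seq), size=n_sub, replace=False)
        out = list(seq)
        for p in positions:
            alt = [b for b in "ACGT" if b != out[p]]
            out[p] = alt[int(rng.integers(3))]
        return "".join(out), corrupted
    if sub == 0 and cfg.ins_rate == 0 and cfg.del_rate == 0:
        return seq, corrupted
    out: List[str] = []
    for base in seq:
        r = rng.random()
        if r < cfg.del_rate:
            continue
        if r < cfg.del_rate + cfg.ins_rate:
            out.append(str(rng.choice(BASES)))
        if rng.random() < sub:
            alt = [b for b in "ACGT" if b != base]
            out.append(alt[int(rng.integers(3))])
        else:
            out.append(base)
    return "".join(out), corrupted
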