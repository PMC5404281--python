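"""Redundancy collapse, merging, gene clustering and read grouping."""

import numpy as np
import pandas as pd
import pytest

from isocensus import (
    SimConfig,
    cluster_genes,
    collapse_loss_ratio,
    coverage_efficiency,
    degrade_and_corrupt,
    ecc_collapse,
    generate,
    group_unmapped,
    merge_libraries,
    tssc_collapse,
)

from conftest import make_transcript, random_transcripts


def _groups_as_sets(groups):
    return {frozenset(g.members) for g in groups}


def brute_force_closure(transcripts, pair_fn):
    """Equivalence closure of a pairwise relation, by repeated merging."""
    groups = [{t.id} for t in transcripts]
    by_id = {t.id: t for t in transcripts}
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(
                    pair_fn(by_id[a], by_id[b])
                    for a in groups[i]
                    for b in groups[j]
                ):
                    groups[i] |= groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(g) for g in groups}


def tssc_pair(a, b):
    if a.chrom != b.chrom or a.strand != b.strand or a.tts != b.tts:
        return False
    if a.n_exons == 1 and b.n_exons == 1:
        return a.span.contains(b.span) or b.span.contains(a.span)
    return a.junctions == b.junctions


def ecc_pair(a, b):
    if a.chrom != b.chrom or a.strand != b.strand or a.tts != b.tts:
        return False
    if a.n_exons == 1 and b.n_exons == 1:
        return a.span.contains(b.span) or b.span.contains(a.span)
    if a.n_exons == 1 or b.n_exons == 1:
        multi, single = (a, b) if a.n_exons > 1 else (b, a)
        return multi.last_exon.contains(single.exons[0])
    short, long = (a, b) if a.n_exons <= b.n_exons else (b, a)
    cs, cl = short.junctions, long.junctions
    tail = cl[len(cl) - len(cs):] if a.strand == "+" else cl[: len(cs)]
    return cs == tail


class TestTsscCollapse:
    def test_varying_tss_collapses_to_longest(self):
        t1 = make_transcript("T1", [(100, 200), (300, 400), (500, 600)])
        t2 = make_transcript("T2", [(150, 200), (300, 400), (500, 600)])
        groups = tssc_collapse([t1, t2])
        assert len(groups) == 1
        assert groups[0].representative.id == "T1"

    def test_missing_first_exon_not_collapsed(self):
        t1 = make_transcript("T1", [(100, 200), (300, 400), (500, 600)])
        t3 = make_transcript("T3", [(300, 400), (500, 600)])
        assert len(tssc_collapse([t1, t3])) == 2

    def test_distinct_tts_never_collapsed(self):
        t1 = make_transcript("T1", [(100, 200), (300, 400)])
        t2 = make_transcript("T2", [(100, 200), (300, 450)])
        assert len(tssc_collapse([t1, t2])) == 2

    def test_matches_pairwise_closure_oracle(self):
        rng = np.random.default_rng(11)
        ts = _collapsible_population(rng, 200)
        got = _groups_as_sets(tssc_collapse(ts))
        assert got == brute_force_closure(ts, tssc_pair)


class TestEccCollapse:
    def test_cascade_groups_three(self):
        t1 = make_transcript("T1", [(100, 200), (300, 400), (500, 600)])
        t2 = make_transcript("T2", [(150, 200), (300, 400), (500, 600)])
        t3 = make_transcript("T3", [(300, 400), (500, 600)])
        groups = ecc_collapse([t1, t2, t3])
        assert len(groups) == 1
        assert groups[0].representative.id == "T1"
        assert groups[0].members == {"T1", "T2", "T3"}

    def test_minus_strand_suffix_is_genomic_left(self):
        # on the minus strand the 3' end is the genomic left
        t1 = make_transcript("T1", [(100, 200), (300, 400), (500, 600)], "-")
        t3 = make_transcript("T3", [(100, 200), (300, 400)], "-")  # 5'-degraded
        assert len(ecc_collapse([t1, t3])) == 1
        # degraded at the 3' side instead: not collapsible
        t4 = make_transcript("T4", [(300, 400), (500, 600)], "-")
        assert len(ecc_collapse([t1, t4])) == 2

    def test_single_exon_into_terminal_exon(self):
        t1 = make_transcript("T1", [(100, 200), (300, 600)])
        s = make_transcript("S", [(450, 600)])
        assert len(ecc_collapse([t1, s])) == 1
        s2 = make_transcript("S2", [(450, 650)])  # TTS differs
        assert len(ecc_collapse([t1, s2])) == 2

    def test_ecc_never_exceeds_tssc(self):
        rng = np.random.default_rng(13)
        for seed in range(5):
            ts = _collapsible_population(np.random.default_rng(seed), 120)
            assert len(ecc_collapse(ts)) <= len(tssc_collapse(ts))

    def test_matches_pairwise_closure_oracle(self):
        rng = np.random.default_rng(17)
        ts = _collapsible_population(rng, 200)
        got = _groups_as_sets(ecc_collapse(ts))
        assert got == brute_force_closure(ts, ecc_pair)

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(19)
        ts = _collapsible_population(rng, 150)
        reps = [g.representative for g in ecc_collapse(ts)]
        again = ecc_collapse(reps)
        assert {g.representative.id for g in again} == {t.id for t in reps}
        shuffled = list(ts)
        rng.shuffle(shuffled)
        assert _groups_as_sets(ecc_collapse(shuffled)) == _groups_as_sets(
            ecc_collapse(ts)
        )

    def test_restores_planted_predegradation_count(self):
        # single-isoform genes: every degraded copy is unambiguous, so the
        # cascade restores exactly the planted transcript count
        cfg = SimConfig(seed=41, n_genes=150, copies_per_transcript=2,
                        degradation_rate=0.5, p_embryo=0.0,
                        p_both_libraries=0.0, p_mt_coding=0.0, p_mt_lnc=0.0)
        genome, truth = generate(cfg)
        reads = [r.model for r in degrade_and_corrupt(genome, truth)]
        assert len(ecc_collapse(reads)) == len(truth.transcripts)


def _collapsible_population(rng, n):
    """Random transcripts with shared junction scaffolds and 5' truncations."""
    out = []
    scaffolds = []
    for s in range(max(3, n // 20)):
        base = 1000 * s
        k = int(rng.integers(2, 5))
        exons = []
        pos = base
        for _ in range(k):
            exons.append((pos, pos + int(rng.integers(30, 80))))
            pos = exons[-1][1] + int(rng.integers(30, 60))
        scaffolds.append(exons)
    for i in range(n):
        exons = [list(e) for e in scaffolds[int(rng.integers(len(scaffolds)))]]
        drop = int(rng.integers(0, len(exons)))
        exons = exons[drop:]
        exons[0][0] -= int(rng.integers(0, 25))
        if rng.random() < 0.3:
            exons[-1][1] += int(rng.integers(1, 3)) * 40
        strand = "+" if rng.random() < 0.7 else "-"
        out.append(make_transcript(f"c{i:04d}", [tuple(e) for e in exons], strand))
    return out


class TestLossRatioAndCoverage:
    @pytest.mark.parametrize(
        "pre,post,expect",
        [(199_560, 80_814, 59.5), (199_560, 55_932, 72.0), (500, 500, 0.0)],
    )
    def test_collapse_loss_ratio(self, pre, post, expect):
        assert round(collapse_loss_ratio(pre, post), 1) == expect

    def test_zero_pre_count_rejected(self):
        with pytest.raises(ValueError):
            collapse_loss_ratio(0, 0)

    @pytest.mark.parametrize(
        "unique,reads,expect",
        [(55_315, 482_325, 11.5), (31_081, 1_566_465, 2.0), (77, 77, 100.0)],
    )
    def test_coverage_efficiency(self, unique, reads, expect):
        assert coverage_efficiency(unique, reads) == expect


class TestMergeLibraries:
    def _pair(self, shift_internal=0, shift_start=0, shift_end=0):
        a = make_transcript("a1", [(100, 200), (300, 400), (500, 600)])
        b = make_transcript(
            "b1",
            [
                (100 + shift_start, 200 + shift_internal),
                (300 + shift_internal, 400),
                (500, 600 + shift_end),
            ],
        )
        return a, b

    def test_within_tolerance_merges_keeping_earlier_start(self):
        a, b = self._pair(shift_internal=5, shift_start=15)
        merged, records = merge_libraries([a], [b])
        assert len(merged) == 1 and merged[0].id == "a1"
        assert records[0].kept_id == "a1" and records[0].merged_ids == ["b1"]

    def test_boundary_shift_of_exactly_ten_not_merged(self):
        a, b = self._pair(shift_internal=10)
        merged, records = merge_libraries([a], [b])
        assert len(merged) == 2 and not records

    def test_end_shift_of_exactly_twenty_not_merged(self):
        a, b = self._pair(shift_end=20)
        merged, _ = merge_libraries([a], [b])
        assert len(merged) == 2

    def test_merged_pairs_to_shared_arithmetic(self):
        # N merged transcripts across two sets correspond to N/2 shared models
        rng = np.random.default_rng(23)
        shared = random_transcripts(rng, 30, strands=("+",))
        only_a = [make_transcript(f"A{i}", [(10_000 + 500 * i, 10_000 + 500 * i + 80)])
                  for i in range(10)]
        only_b = [make_transcript(f"B{i}", [(30_000 + 500 * i, 30_000 + 500 * i + 80)])
                  for i in range(7)]
        a_side = [make_transcript("a_" + t.id, [(e.start, e.end) for e in t.exons])
                  for t in shared] + only_a
        b_side = [make_transcript("b_" + t.id, [(e.start, e.end) for e in t.exons])
                  for t in shared] + only_b
        merged, records = merge_libraries(a_side, b_side)
        merged_transcripts = 2 * len(records)
        assert merged_transcripts // 2 == len(records)
        assert len(merged) == len(a_side) + len(b_side) - len(records)

    def test_symmetric_merged_count(self):
        rng = np.random.default_rng(29)
        a = random_transcripts(rng, 40)
        b = random_transcripts(np.random.default_rng(30), 40)
        b = [make_transcript("b" + t.id, [(e.start, e.end) for e in t.exons],
                             t.strand) for t in b]
        m1, r1 = merge_libraries(a, b)
        m2, r2 = merge_libraries(b, a)
        assert len(m1) == len(m2) and len(r1) == len(r2)


class TestClusterGenes:
    def test_same_strand_overlap_joins(self):
        a = make_transcript("a", [(100, 200)])
        b = make_transcript("b", [(199, 300)])
        assert len(cluster_genes([a, b])) == 1

    def test_opposite_strands_stay_separate(self):
        a = make_transcript("a", [(100, 200)], "+")
        b = make_transcript("b", [(150, 250)], "-")
        assert len(cluster_genes([a, b])) == 2

    def test_transitive_chain_is_one_gene(self):
        a = make_transcript("a", [(0, 100)])
        b = make_transcript("b", [(90, 200)])
        c = make_transcript("c", [(190, 300)])  # a and c do not overlap
        genes = cluster_genes([a, b, c])
        assert len(genes) == 1

    def test_touching_spans_do_not_join(self):
        a = make_transcript("a", [(0, 100)])
        b = make_transcript("b", [(100, 200)])
        assert len(cluster_genes([a, b])) == 2

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(31)
        ts = random_transcripts(rng, 500)
        genes = cluster_genes(ts)

        def overlap_pair(a, b):
            return (
                a.strand == b.strand
                and a.span.start < b.span.end
                and b.span.start < a.span.end
            )

        want = brute_force_closure(ts, overlap_pair)
        got = {frozenset(t.id for t in g.transcripts) for g in genes}
        assert got == want

    def test_deterministic_ids_by_position(self):
        ts = [
            make_transcript("z", [(5000, 5100)]),
            make_transcript("a", [(100, 200)]),
        ]
        genes = cluster_genes(ts)
        assert genes[0].id == "gene000001"
        assert genes[0].transcripts[0].id == "a"


class TestGroupUnmapped:
    def test_no_hits_all_singletons(self):
        hits = pd.DataFrame(columns=["read_a", "read_b", "strand_a", "strand_b"])
        groups = group_unmapped(hits, reads=[f"r{i}" for i in range(5)])
        assert len(groups) == 5

    def test_same_strand_chain(self):
        hits = pd.DataFrame(
            [
                {"read_a": "a", "read_b": "b", "strand_a": "+", "strand_b": "+"},
                {"read_a": "b", "read_b": "c", "strand_a": "-", "strand_b": "-"},
                {"read_a": "c", "read_b": "d", "strand_a": "+", "strand_b": "-"},
            ]
        )
        groups = group_unmapped(hits)
        assert {frozenset(g) for g in groups} == {
            frozenset({"a", "b", "c"}),
            frozenset({"d"}),
        }

    def test_matches_bfs_oracle(self):
        rng = np.random.default_rng(37)
        reads = [f"r{i}" for i in range(120)]
        rows = []
        for _ in range(200):
            a, b = rng.choice(reads, size=2, replace=False)
            rows.append(
                {
                    "read_a": a,
                    "read_b": b,
                    "strand_a": "+" if rng.random() < 0.5 else "-",
                    "strand_b": "+" if rng.random() < 0.5 else "-",
                }
            )
        hits = pd.DataFrame(rows)
        got = {frozenset(g) for g in group_unmapped(hits, reads)}

        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(reads)
        for r in rows:
            if r["strand_a"] == r["strand_b"]:
                g.add_edge(r["read_a"], r["read_b"])
        want = {frozenset(c) for c in nx.connected_components(g)}
        assert got == want
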