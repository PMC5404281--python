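import numpy as np
import pytest

from isocensus import SimConfig, generate
from isocensus.model import GenomicInterval, TranscriptModel


def make_transcript(tid, exons, strand="+", chrom="chr1", **kw):
    """Shorthand transcript constructor for hand-built fixtures."""
    return TranscriptModel(
        id=tid,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        **kw,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small mixed simulation shared across read-only tests."""
    cfg = SimConfig(seed=101, n_genes=120)
    genome, truth = generate(cfg)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def small_annotation(small_sim):
    _, _, truth = small_sim
    return truth.annotation()


def random_transcripts(rng, n, chrom="chr1", strands=("+", "-")):
    """Random (possibly overlapping) transcript models for oracle tests."""
    out = []
    for i in range(n):
        start = int(rng.integers(0, 5000))
        n_ex = int(rng.integers(1, 5))
        exons = []
        pos = start
        for _ in range(n_ex):
            length = int(rng.integers(20, 120))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(20, 100))
        out.append(
            make_transcript(
                f"r{i:04d}", exons, strand=strands[int(rng.integers(len(strands)))],
                chrom=chrom,
            )
        )
    return out
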