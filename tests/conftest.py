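"""Shared fixtures and independent brute-force oracles.

The oracles re-derive alignment candidates, class labels and bin vectors
from first principles (exhaustive scans, explicit per-base loops) so the
package's indexed/vectorized implementations can be checked against
machinery that shares none of their code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from nemasrna.annotation import FeatureRecord, GenomeAnnotation, generate_annotation
from nemasrna.config import PipelineConfig
from nemasrna.genome import ToyGenome, generate_genome, reverse_complement


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig(seed=7)


@pytest.fixture(scope="session")
def toy_genome() -> ToyGenome:
    return generate_genome(1, 50_000, gc_fraction=0.36, seed=7)


@pytest.fixture(scope="session")
def toy_annotation(toy_genome) -> GenomeAnnotation:
    return generate_annotation(
        toy_genome,
        {
            "protein_coding": 12,
            "piRNA_21ur": 8,
            "miRNA_mature": 5,
            "rRNA": 2,
            "tRNA": 2,
            "transposon": 3,
            "lincRNA": 2,
            "pseudogene": 2,
        },
        min_gap=60,
        seed=11,
    )


# ---------------------------------------------------------------------------
# oracle: exhaustive <=1-mismatch placement scan


def brute_force_placements(insert: str, genome: ToyGenome, max_mm: int = 1):
    """All (chrom, start, strand, mm) placements via a full O(L*n) scan."""
    out = []
    for chrom in genome.chrom_names:
        ref = np.frombuffer(genome[chrom].encode(), dtype=np.uint8)
        for strand in "+-":
            q = insert if strand == "+" else reverse_complement(insert)
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            L = len(q)
            if L > ref.size:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref, L)
            mm = (windows != qa).sum(axis=1)
            for pos in np.flatnonzero(mm <= max_mm):
                out.append((chrom, int(pos), strand, int(mm[pos])))
    return sorted(out)


def brute_force_best_stratum(insert: str, genome: ToyGenome, max_mm: int = 1):
    cands = brute_force_placements(insert, genome, max_mm)
    if not cands:
        return []
    best = min(c[3] for c in cands)
    return [c for c in cands if c[3] == best]


# ---------------------------------------------------------------------------
# oracle: first-principles classifier


_STRUCT = {"rRNA", "tRNA", "snRNA", "snoRNA"}
_TARGETS = {"protein_coding", "lincRNA", "pseudogene", "transposon"}


def brute_force_classify(read, annotation: GenomeAnnotation):
    """Re-derive overlap, relative strand, length and 5' nucleotide checks
    from the raw records, with the structural > miRNA > 21U > 22G/26G
    hierarchy and largest-overlap-then-id tie-break."""
    length = len(read.insert)
    first = read.insert[0]
    hits = []
    for f in annotation.features:
        if f.chrom != read.chrom:
            continue
        ov = 0
        for s, e in f.exons:
            ov += max(0, min(read.start + length, e) - max(read.start, s))
        if ov > 0:
            hits.append((f, ov))

    def pick(cands):
        return sorted(cands, key=lambda t: (-t[1], t[0].feature_id))[0][0]

    sense = [(f, ov) for f, ov in hits if f.strand == read.strand]
    anti = [(f, ov) for f, ov in hits if f.strand != read.strand]

    structural = [(f, ov) for f, ov in sense if f.biotype in _STRUCT]
    if structural:
        return "structural", pick(structural).feature_id
    mirna = [
        (f, ov) for f, ov in sense
        if f.biotype == "miRNA_mature" and 21 <= length <= 24
    ]
    if mirna:
        return "miRNA", pick(mirna).feature_id
    piw = [
        (f, ov) for f, ov in sense
        if f.biotype == "piRNA_21ur" and length == 21 and first == "T"
    ]
    if piw:
        return "21U", pick(piw).feature_id
    if length in (22, 26) and first == "G":
        targets = [(f, ov) for f, ov in anti if f.biotype in _TARGETS]
        if targets:
            return ("22G" if length == 22 else "26G"), pick(targets).feature_id
    return "unclassified", None


# ---------------------------------------------------------------------------
# oracle: explicit per-base bin accumulator


def brute_force_bins(feature: FeatureRecord, reads, n_bins: int = 100):
    """Per-base coverage accumulated with explicit loops, then averaged
    into floor-edged bins oriented 5'->3'."""
    L = feature.exonic_length
    cov = [0.0] * L
    tpos = []  # genomic position of transcript coordinate t
    exons = feature.exons if feature.strand == "+" else list(reversed(feature.exons))
    for s, e in exons:
        rng = range(s, e) if feature.strand == "+" else range(e - 1, s - 1, -1)
        tpos.extend(rng)
    g2t = {g: t for t, g in enumerate(tpos)}
    for c in reads:
        read = getattr(c, "read", c)
        if read.chrom != feature.chrom:
            continue
        for g in range(read.start, read.end):
            t = g2t.get(g)
            if t is not None:
                cov[t] += 1.0
    bins = []
    for b in range(1, n_bins + 1):
        lo = (b - 1) * L // n_bins
        hi = b * L // n_bins
        bins.append(sum(cov[lo:hi]) / (hi - lo) if hi > lo else 0.0)
    return np.array(bins)
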