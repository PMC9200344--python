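"""Strand-aware, biotype-labeled feature annotation over a genome.

Features carry sorted, disjoint exon intervals in 0-based half-open
coordinates; conversion to/from the GTF convention (1-based, closed)
happens only at the file boundary. Biotypes follow the C. elegans
small-RNA vocabulary: structural loci (rRNA, tRNA, snRNA, snoRNA),
mature miRNAs, piRNA "21ur" loci, and the 22G/26G target space of
protein-coding genes, lincRNAs, pseudogenes and transposons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

BIOTYPES = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "miRNA_mature",
    "piRNA_21ur",
    "protein_coding",
    "lincRNA",
    "pseudogene",
    "transposon",
)

STRUCTURAL_BIOTYPES = frozenset({"rRNA", "tRNA", "snRNA", "snoRNA"})
#: exonic targets of antisense 22G/26G-RNAs (transposons handled separately)
GENIC_TARGET_BIOTYPES = frozenset({"protein_coding", "lincRNA", "pseudogene"})

# toy locus length ranges per biotype (bases); loosely modeled on the real
# size classes so reads, metagene bins and overlaps behave like the organism's
_BIOTYPE_LENGTHS = {
    "rRNA": (100, 150),
    "tRNA": (70, 90),
    "snRNA": (100, 180),
    "snoRNA": (70, 140),
    "miRNA_mature": (22, 22),
    "piRNA_21ur": (21, 21),
    "protein_coding": (800, 2400),
    "lincRNA": (400, 1200),
    "pseudogene": (400, 1000),
    "transposon": (600, 1600),
}


@dataclass
class FeatureRecord:
    feature_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, disjoint
    biotype: str
    family: str | None = None  # transposon-family label, if any

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 > s1:
                raise ValueError(f"overlapping exons in {self.feature_id}")
        if any(s >= e for s, e in self.exons):
            raise ValueError(f"empty exon in {self.feature_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Map a genomic position inside an exon to the 5'->3' transcript
        coordinate of the concatenated exons; None if intronic/outside."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos < e:
                t = offset + (gpos - s)
                if self.strand == "-":
                    t = self.exonic_length - 1 - t
                return t
            offset += e - s
        return None


class GenomeAnnotation:
    """Set of features with an interval index for strand-aware overlap."""

    def __init__(self, features: list[FeatureRecord]):
        ids = [f.feature_id for f in features]
        if len(set(ids)) != len(ids):
            raise ValueError("feature ids must be unique")
        self.features = list(features)
        self.by_id = {f.feature_id: f for f in self.features}
        self._trees: dict[str, IntervalTree] = {}
        for f in self.features:
            tree = self._trees.setdefault(f.chrom, IntervalTree())
            for s, e in f.exons:
                tree.addi(s, e, f)

    def __len__(self) -> int:
        return len(self.features)

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[FeatureRecord, int]]:
        """Features with >= 1 exonic base shared with [start, end).

        Returns (feature, overlap_bases) pairs, overlap summed over exons.
        """
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        acc: dict[str, int] = {}
        feats: dict[str, FeatureRecord] = {}
        for iv in tree.overlap(start, end):
            f = iv.data
            ov = min(end, iv.end) - max(start, iv.begin)
            acc[f.feature_id] = acc.get(f.feature_id, 0) + ov
            feats[f.feature_id] = f
        return [(feats[k], acc[k]) for k in sorted(acc)]

    # -- GTF boundary -------------------------------------------------

    def write_gtf(self, path: str | Path, source: str = "nemasrna") -> None:
        with open(path, "w") as fh:
            for f in sorted(self.features, key=lambda x: (x.chrom, x.start, x.feature_id)):
                for s, e in f.exons:
                    attrs = f'gene_id "{f.feature_id}"; gene_biotype "{f.biotype}";'
                    if f.family:
                        attrs += f' family_id "{f.family}";'
                    fh.write(
                        "\t".join(
                            [f.chrom, source, "exon", str(s + 1), str(e),
                             ".", f.strand, ".", attrs]
                        )
                        + "\n"
                    )

    @classmethod
    def read_gtf(
        cls,
        path: str | Path,
        biotype_key: str = "gene_biotype",
        id_key: str = "gene_id",
    ) -> "GenomeAnnotation":
        feats: dict[str, dict] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) != 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
                chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols
                if ftype != "exon":
                    continue
                kv = dict(re.findall(r'(\w+) "([^"]*)"', attrs))
                if id_key not in kv:
                    raise ValueError(f"{path}:{lineno}: missing {id_key} attribute")
                fid = kv[id_key]
                rec = feats.setdefault(
                    fid,
                    {"chrom": chrom, "strand": strand,
                     "biotype": kv.get(biotype_key, "protein_coding"),
                     "family": kv.get("family_id"), "exons": []},
                )
                rec["exons"].append((int(start) - 1, int(end)))
        return cls(
            [
                FeatureRecord(fid, r["chrom"], r["strand"], r["exons"],
                              r["biotype"], r["family"])
                for fid, r in feats.items()
            ]
        )


def generate_annotation(
    genome,
    counts_per_biotype: dict[str, int],
    min_gap: int = 50,
    seed: int = 0,
    exons_per_gene: tuple[int, int] = (1, 1),
    intron_length: int = 60,
) -> GenomeAnnotation:
    """Place non-overlapping features of the requested biotypes on the genome.

    Features get a random strand, 1-3 exons (single-exon by default so
    gene-body and exon-concatenated coordinates coincide), and unique ids.
    Deterministic under the seed; raises if the genome cannot hold them.
    """
    unknown = set(counts_per_biotype) - set(BIOTYPES)
    if unknown:
        raise ValueError(f"unknown biotypes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    jobs: list[str] = []
    for bt in BIOTYPES:  # fixed order for determinism
        jobs.extend([bt] * counts_per_biotype.get(bt, 0))
    order = rng.permutation(len(jobs))
    jobs = [jobs[i] for i in order]

    chrom_cursor = {name: 0 for name in genome.chrom_names}
    counters: dict[str, int] = {}
    features: list[FeatureRecord] = []
    chrom_cycle = list(genome.chrom_names)
    ci = 0
    for bt in jobs:
        lo, hi = _BIOTYPE_LENGTHS[bt]
        length = int(rng.integers(lo, hi + 1))
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        if length < 3 * n_ex:
            n_ex = 1
        span = length + (n_ex - 1) * intron_length
        placed = False
        for _ in range(len(chrom_cycle)):
            chrom = chrom_cycle[ci % len(chrom_cycle)]
            start = chrom_cursor[chrom] + min_gap + int(rng.integers(0, min_gap + 1))
            if start + span <= genome.length(chrom):
                chrom_cursor[chrom] = start + span
                placed = True
                break
            ci += 1
        if not placed:
            raise ValueError(
                "genome too small to place all requested features with min_gap"
            )
        ci += 1
        counters[bt] = counters.get(bt, 0) + 1
        fid = f"{bt}_{counters[bt]:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _split_exons(start, length, n_ex, intron_length, rng)
        family = f"TcToy{1 + counters[bt] % 3}" if bt == "transposon" else None
        features.append(FeatureRecord(fid, chrom, strand, exons, bt, family))
    return GenomeAnnotation(features)


def _split_exons(start, length, n_ex, intron_length, rng):
    if n_ex == 1:
        return [(start, start + length)]
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_ex - 1, replace=False))
    sizes = np.diff(np.concatenate([[0], cuts, [length]]))
    exons, pos = [], start
    for sz in sizes:
        exons.append((pos, pos + int(sz)))
        pos += int(sz) + intron_length
    return exons


def plant_overlap_fixture(
    annotation: GenomeAnnotation, host_id: str, length: int = 700, seed: int = 0
) -> GenomeAnnotation:
    """Plant a transposon inside a protein-coding host gene's span.

    Mirrors the real-genome situation of a transposable element embedded in
    a gene (sense or antisense), used to exercise classification tie-breaks.
    """
    rng = np.random.default_rng(seed)
    host = annotation.by_id[host_id]
    if host.end - host.start < length + 20:
        raise ValueError("host gene too short for the planted transposon")
    start = host.start + 10 + int(rng.integers(0, host.end - host.start - length - 10))
    strand = "+" if rng.random() < 0.5 else "-"
    n = 1 + sum(1 for f in annotation.features if f.biotype == "transposon")
    tn = FeatureRecord(
        f"transposon_planted_{n:04d}", host.chrom, strand,
        [(start, start + length)], "transposon", family="Turmoil_toy",
    )
    return GenomeAnnotation(annotation.features + [tn])
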