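"""Ungapped placement of small-RNA inserts under a best-stratum,
one-mismatch, report-one policy, plus SAM ingestion/emission.

The policy mirrors the classic short-read behaviour for small RNAs:
enumerate every genomic placement (either strand) with at most one
substitution, keep only the best stratum (0-mismatch placements if any
exist, else 1-mismatch), and report exactly one placement chosen
uniformly at random — reproducibly under the pipeline seed — flagging
the read as a multimapper when the stratum holds more than one
placement. Indels are not considered.

The index stores exact k-mer positions. The aligner finds candidates by
a pigeonhole split: an insert with at most one mismatch has at least one
mismatch-free half, and a half of length >= k is discovered through its
leading k-mer. The default k (9) is at most half the shortest insert
(18 nt), which makes the search exhaustive; an exhaustive scan oracle is
used in the tests to confirm this.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .config import PipelineConfig
from .genome import ToyGenome, reverse_complement


@dataclass
class AlignedRead:
    read_id: str
    insert: str  # as sequenced, 5'->3'
    chrom: str
    start: int  # 0-based leftmost aligned base
    strand: str  # '+' or '-'
    mismatch_count: int
    multimap_flag: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.insert)


class KmerIndex:
    """Exact-match index of every genomic k-mer (both strands retrievable)."""

    def __init__(self, genome: ToyGenome, k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.genome = genome
        self.k = k
        self._fwd: dict[str, list[tuple[str, int]]] = {}
        for chrom in genome.chrom_names:
            seq = genome[chrom]
            for i in range(len(seq) - k + 1):
                self._fwd.setdefault(seq[i : i + k], []).append((chrom, i))

    @property
    def n_forward_positions(self) -> int:
        return sum(len(v) for v in self._fwd.values())

    def forward_positions(self, kmer: str) -> list[tuple[str, int]]:
        """Forward-strand occurrences (chrom, 0-based start)."""
        return self._fwd.get(kmer, [])

    def reverse_positions(self, kmer: str) -> list[tuple[str, int]]:
        """Reverse-strand occurrences, reported as the forward-strand
        coordinate of the leftmost base they cover."""
        return self._fwd.get(reverse_complement(kmer), [])

    def positions(self, kmer: str) -> dict[str, list[tuple[str, int]]]:
        return {"+": self.forward_positions(kmer), "-": self.reverse_positions(kmer)}


def build_index(genome: ToyGenome, k: int = 9) -> KmerIndex:
    return KmerIndex(genome, k)


def _exact_occurrences(index: KmerIndex, pattern: str):
    """All forward-genome occurrences of `pattern` (len >= index.k)."""
    lead = pattern[: index.k]
    out = []
    for chrom, pos in index.forward_positions(lead):
        seq = index.genome[chrom]
        if seq[pos : pos + len(pattern)] == pattern:
            out.append((chrom, pos))
    return out


def _count_mismatches(a: str, b: str, cap: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return mm
    return mm


def candidate_placements(
    insert: str, index: KmerIndex, max_mismatches: int = 1
) -> list[tuple[str, int, str, int]]:
    """All (chrom, start, strand, n_mismatches) placements of the insert
    with at most `max_mismatches` substitutions, on either strand."""
    L = len(insert)
    if index.k > L // 2 and max_mismatches > 0:
        raise ValueError(
            f"index k={index.k} exceeds half the insert length {L}; "
            "one-mismatch search would not be exhaustive"
        )
    found: dict[tuple[str, int, str], int] = {}
    for strand in "+-":
        q = insert if strand == "+" else reverse_complement(insert)
        mid = L // 2
        starts: set[tuple[str, int]] = set()
        for off, half in ((0, q[:mid]), (mid, q[mid:])):
            for chrom, pos in _exact_occurrences(index, half):
                starts.add((chrom, pos - off))
        for chrom, start in starts:
            if start < 0 or start + L > index.genome.length(chrom):
                continue
            ref = index.genome[chrom][start : start + L]
            mm = _count_mismatches(q, ref, max_mismatches)
            if mm <= max_mismatches:
                key = (chrom, start, strand)
                if key not in found or mm < found[key]:
                    found[key] = mm
    return sorted((c, s, st, mm) for (c, s, st), mm in found.items())


def align_insert(
    insert: str,
    index: KmerIndex,
    cfg: PipelineConfig,
    read_id: str = "",
) -> AlignedRead | None:
    """Best-stratum, report-one alignment of one insert.

    The random choice among equally good placements is keyed on
    (pipeline seed, insert), so it is reproducible and independent of
    the order in which reads are aligned. Returns None when no placement
    has <= cfg.max_mismatches substitutions; raises on non-ACGT inserts.
    """
    if set(insert) - set("ACGT"):
        raise AmbiguousBaseError(f"non-ACGT base in insert {read_id or insert!r}")
    cands = candidate_placements(insert, index, cfg.max_mismatches)
    if not cands:
        return None
    best = min(mm for *_, mm in cands)
    stratum = [c for c in cands if c[3] == best]
    if len(stratum) == 1:
        chrom, start, strand, mm = stratum[0]
        return AlignedRead(read_id, insert, chrom, start, strand, mm, False)
    rng = np.random.default_rng([cfg.seed, zlib.crc32(insert.encode())])
    chrom, start, strand, mm = stratum[int(rng.integers(len(stratum)))]
    return AlignedRead(read_id, insert, chrom, start, strand, mm, True)


class AmbiguousBaseError(ValueError):
    pass


def align_reads(
    reads: list[tuple[str, str]], index: KmerIndex, cfg: PipelineConfig
) -> tuple[list[AlignedRead], "pd.DataFrame"]:
    """Align (read_id, insert) pairs; returns alignments + unaligned log.

    Results are cached per distinct insert sequence, so duplicated
    small-RNA species cost one index search.
    """
    import pandas as pd

    cache: dict[str, AlignedRead | str | None] = {}
    out: list[AlignedRead] = []
    log = []
    for read_id, insert in reads:
        if insert in cache:
            res = cache[insert]
        else:
            try:
                res = align_insert(insert, index, cfg)
            except AmbiguousBaseError:
                res = "ambiguous_base"
            cache[insert] = res
        if isinstance(res, AlignedRead):
            out.append(
                AlignedRead(read_id, insert, res.chrom, res.start, res.strand,
                            res.mismatch_count, res.multimap_flag)
            )
        else:
            log.append((read_id, res if isinstance(res, str) else "unaligned"))
    return out, pd.DataFrame(log, columns=["read_id", "reason"])


# ---------------------------------------------------------------------------
# SAM boundary (1-based SAM <-> 0-based internal; FLAG 0x10 <-> strand)


def _sam_header(genome: ToyGenome) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": genome.length(c)} for c in genome.chrom_names],
    }


def write_alignments(
    alignments: list[AlignedRead], genome: ToyGenome, path: str | Path
) -> None:
    header = pysam.AlignmentHeader.from_dict(_sam_header(genome))
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            rec = pysam.AlignedSegment(header)
            rec.query_name = aln.read_id
            rec.flag = 16 if aln.strand == "-" else 0
            rec.reference_id = genome.chrom_names.index(aln.chrom)
            rec.reference_start = aln.start
            rec.mapping_quality = 255
            rec.cigarstring = f"{len(aln.insert)}M"
            seq = aln.insert if aln.strand == "+" else reverse_complement(aln.insert)
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            rec.set_tag("NM", aln.mismatch_count)
            rec.set_tag("ZM", 1 if aln.multimap_flag else 0)
            fh.write(rec)


def read_alignments(
    path: str | Path, genome: ToyGenome | None = None
) -> list[AlignedRead]:
    """Ingest a SAM file as AlignedReads.

    Strand comes from FLAG bit 0x10 and the stored sequence is flipped
    back to sequencing orientation; the mismatch count comes from the NM
    tag, recomputed against the genome when the tag is missing.
    """
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for i, rec in enumerate(fh, 1):
            if rec.is_unmapped:
                continue
            try:
                strand = "-" if rec.is_reverse else "+"
                seq = rec.query_sequence
                insert = reverse_complement(seq) if strand == "-" else seq
                if rec.has_tag("NM"):
                    mm = int(rec.get_tag("NM"))
                elif genome is not None:
                    ref = genome[rec.reference_name][
                        rec.reference_start : rec.reference_start + len(seq)
                    ]
                    mm = sum(a != b for a, b in zip(seq, ref))
                else:
                    raise ValueError("record lacks NM tag and no genome given")
                multi = bool(rec.get_tag("ZM")) if rec.has_tag("ZM") else False
                out.append(
                    AlignedRead(
                        rec.query_name, insert, rec.reference_name,
                        rec.reference_start, strand, mm, multi,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"malformed SAM record #{i}: {exc}") from exc
    return out
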