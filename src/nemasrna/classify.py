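"""Rule-based assignment of aligned reads to small-RNA classes and loci.

Classes follow the C. elegans conventions:

* structural — sense over rRNA, tRNA, snRNA or snoRNA loci (any length);
* miRNA — 21-24 nt, sense over mature miRNA loci;
* 21U — exactly 21 nt, 5' T, sense over piRNA (21ur) loci;
* 22G / 26G — exactly 22 / 26 nt, 5' G, antisense to transposons or to
  exons of protein-coding genes, lincRNAs and pseudogenes.

Rules are evaluated in a fixed hierarchy (structural > miRNA > 21U >
22G/26G): structural contaminants are removed before class
quantification, as is standard small-RNA practice. A read overlaps a
locus when it shares >= 1 exonic base with it; ties within a rule are
broken by the largest overlap, then lexicographic feature id, making the
outcome deterministic and order-independent. "Starts with" refers to
the read's 5' nucleotide in sequencing orientation. Reads matching no
rule stay unclassified (a valid outcome, excluded from count tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import AlignedRead
from .annotation import (
    GENIC_TARGET_BIOTYPES,
    STRUCTURAL_BIOTYPES,
    FeatureRecord,
    GenomeAnnotation,
)
from .config import PipelineConfig

CLASS_LABELS = ("structural", "miRNA", "21U", "22G", "26G", "unclassified")


@dataclass
class ClassifiedRead:
    read: AlignedRead
    sclass: str
    feature_id: str | None

    @property
    def sample_fields(self):
        return self.read.read_id


def relative_strand(read: AlignedRead, feature: FeatureRecord) -> str:
    """'sense' iff the read's alignment strand equals the feature strand."""
    return "sense" if read.strand == feature.strand else "antisense"


def _rule_structural(read, feature, cfg):
    return feature.biotype in STRUCTURAL_BIOTYPES and read.strand == feature.strand


def _rule_mirna(read, feature, cfg):
    return (
        feature.biotype == "miRNA_mature"
        and 21 <= len(read.insert) <= 24
        and read.strand == feature.strand
    )


def _rule_21u(read, feature, cfg):
    return (
        feature.biotype == "piRNA_21ur"
        and len(read.insert) == 21
        and read.insert[0] == "T"
        and read.strand == feature.strand
    )


def _rule_22g_26g(read, feature, cfg):
    n = len(read.insert)
    if n not in (22, 26) or read.insert[0] != "G":
        return False
    if read.strand == feature.strand:
        return False
    if feature.biotype in GENIC_TARGET_BIOTYPES:
        return True
    if feature.biotype == "transposon":
        return n == 22 or cfg.allow_26g_transposons
    return False


_RULES = (
    ("structural", _rule_structural),
    ("miRNA", _rule_mirna),
    ("21U", _rule_21u),
    ("22G/26G", _rule_22g_26g),
)


def assign_class(
    read: AlignedRead, annotation: GenomeAnnotation, cfg: PipelineConfig | None = None
) -> ClassifiedRead:
    cfg = cfg or PipelineConfig()
    candidates = annotation.overlapping(read.chrom, read.start, read.end)
    for label, rule in _RULES:
        hits = [(f, ov) for f, ov in candidates if rule(read, f, cfg)]
        if hits:
            # largest overlap, then lexicographic feature id
            f, _ = min(hits, key=lambda t: (-t[1], t[0].feature_id))
            if label == "22G/26G":
                label = "22G" if len(read.insert) == 22 else "26G"
            return ClassifiedRead(read, label, f.feature_id)
    return ClassifiedRead(read, "unclassified", None)


def classify_reads(
    alignments: list[AlignedRead],
    annotation: GenomeAnnotation,
    cfg: PipelineConfig | None = None,
) -> list[ClassifiedRead]:
    cfg = cfg or PipelineConfig()
    alns = alignments
    if not cfg.keep_multimappers:
        alns = [a for a in alns if not a.multimap_flag]
    return [assign_class(a, annotation, cfg) for a in alns]


def classified_to_frame(classified: list[ClassifiedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [c.read.read_id for c in classified],
            "chrom": [c.read.chrom for c in classified],
            "start": [c.read.start for c in classified],
            "strand": [c.read.strand for c in classified],
            "length": [len(c.read.insert) for c in classified],
            "class": [c.sclass for c in classified],
            "feature_id": [c.feature_id for c in classified],
        }
    )


def count_matrix(
    classified_by_sample: dict[str, list[ClassifiedRead]],
    annotation: GenomeAnnotation | None = None,
    class_filter: str | None = None,
    aggregate_families: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-(feature, class) x sample integer counts.

    Each classified read contributes exactly one count to exactly one
    cell; unclassified reads are excluded and tallied separately. With
    `aggregate_families`, transposon copies sharing a family label are
    summed under the family name (requires the annotation).

    Returns (counts with a (feature_id, class) MultiIndex, per-sample
    unclassified counts).
    """
    samples = list(classified_by_sample)
    cells: dict[tuple[str, str], dict[str, int]] = {}
    unclassified = {}
    for sample, reads in classified_by_sample.items():
        n_un = 0
        for c in reads:
            if c.sclass == "unclassified":
                n_un += 1
                continue
            if class_filter and c.sclass != class_filter:
                continue
            fid = c.feature_id
            if aggregate_families and annotation is not None:
                feat = annotation.by_id[fid]
                if feat.biotype == "transposon" and feat.family:
                    fid = feat.family
            row = cells.setdefault((fid, c.sclass), {})
            row[sample] = row.get(sample, 0) + 1
        unclassified[sample] = n_un
    index = pd.MultiIndex.from_tuples(
        sorted(cells) or [], names=["feature_id", "class"]
    )
    mat = pd.DataFrame(
        [[cells[key].get(s, 0) for s in samples] for key in sorted(cells)],
        index=index,
        columns=samples,
        dtype=int,
    )
    return mat, pd.Series(unclassified, name="unclassified")


def class_counts(
    counts: pd.DataFrame, sclass: str
) -> pd.DataFrame:
    """Slice a (feature, class)-indexed matrix down to one class."""
    if len(counts) == 0:
        return counts
    sub = counts.xs(sclass, level="class")
    return sub
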