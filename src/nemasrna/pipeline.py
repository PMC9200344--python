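"""End-to-end toy study: simulate -> preprocess -> align -> classify ->
count -> differential calls -> metagene profiles.

This is the desk-scale composition of all pipeline stages, used by the
examples, the smoke tests and the acceptance script. Everything is
deterministic under a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import align, classify, metagene, preprocess, quantify, simulate
from .annotation import GenomeAnnotation, generate_annotation
from .config import PipelineConfig
from .genome import ToyGenome, generate_genome


@dataclass
class StudyResult:
    genome: ToyGenome
    annotation: GenomeAnnotation
    truth: simulate.SimulationTruth
    truth_table: pd.DataFrame
    cfg: PipelineConfig
    preprocess_stats: dict[str, pd.DataFrame]
    classified: dict[str, list]
    counts: pd.DataFrame
    unclassified: pd.Series
    size_factors: pd.Series
    ma_table: pd.DataFrame
    up: set[str]
    down: set[str]
    truth_up: set[str]
    truth_down: set[str]
    matrices: dict[str, pd.DataFrame] = field(default_factory=dict)


def default_annotation_counts() -> dict[str, int]:
    return {
        "protein_coding": 60,
        "lincRNA": 6,
        "pseudogene": 6,
        "transposon": 8,
        "piRNA_21ur": 30,
        "miRNA_mature": 15,
        "rRNA": 4,
        "tRNA": 6,
        "snRNA": 3,
        "snoRNA": 3,
    }


def default_class_mix() -> dict[str, float]:
    # rough library composition of a worm small-RNA library after
    # ribo-depletion: 22G-dominated, with 21U, miRNA and residual
    # structural reads
    return {"22G": 0.55, "26G": 0.05, "21U": 0.20, "miRNA": 0.12, "structural": 0.08}


def run_toy_study(
    seed: int = 0,
    reads_per_sample: int = 10_000,
    n_replicates: int = 3,
    chrom_length: int = 300_000,
    annotation_counts: dict[str, int] | None = None,
    class_mix: dict[str, float] | None = None,
    frac_up: float = 0.10,
    frac_down: float = 0.10,
    fold_up: float = 4.0,
    fold_down: float = 0.25,
    beta_wt: tuple[float, float] = (2.0, 2.0),
    beta_mut: tuple[float, float] = (2.0, 2.0),
    dispersion: float = 0.05,
    library_layout: str = "raw",
    de_class: str = "22G",
    compute_matrices: bool = False,
) -> StudyResult:
    """Simulate a two-condition small-RNA study and run the full pipeline.

    The deregulation calls are made on the `de_class` count table
    (22G-RNAs by default) and compared against the simulated truth sets.
    """
    cfg = PipelineConfig(seed=seed)
    genome = generate_genome(1, chrom_length, gc_fraction=0.36, seed=seed)
    annotation = generate_annotation(
        genome, annotation_counts or default_annotation_counts(), min_gap=60,
        seed=seed + 1,
    )
    truth = simulate.make_truth(
        annotation,
        class_mix or default_class_mix(),
        reads_per_sample,
        n_replicates=n_replicates,
        dispersion=dispersion,
        frac_26g=0.08,
        frac_up=frac_up,
        frac_down=frac_down,
        fold_up=fold_up,
        fold_down=fold_down,
        beta_wt=beta_wt,
        beta_mut=beta_mut,
        seed=seed + 2,
    )
    reads_by_sample, truth_table = simulate.simulate_reads(
        genome, annotation, truth, library_layout=library_layout
    )

    index = align.build_index(genome, cfg.index_k)
    stats: dict[str, pd.DataFrame] = {}
    classified: dict[str, list] = {}
    for sample, reads in reads_by_sample.items():
        if library_layout == "raw":
            inserts, log = preprocess.preprocess_reads(reads, cfg)
            stats[sample] = preprocess.preprocess_stats(log)
        else:
            inserts = reads
        aligned, _unaligned = align.align_reads(inserts, index, cfg)
        classified[sample] = classify.classify_reads(aligned, annotation, cfg)

    counts, unclassified = classify.count_matrix(classified)
    de_counts = classify.class_counts(counts, de_class)
    s = quantify.size_factors(de_counts)
    condition = pd.Series(
        ["wt" if c.startswith("wt") else "mutant" for c in de_counts.columns],
        index=de_counts.columns,
    )
    res = quantify.nb_test(de_counts, s, condition)
    ma_table = quantify.call_deregulated(res, cfg)
    up, down = quantify.deregulated_sets(ma_table)

    tf = truth.frame()
    de_truth = tf[tf["class"] == de_class]
    truth_up = set(de_truth.loc[de_truth["fold_change"] > 1, "feature_id"])
    truth_down = set(de_truth.loc[de_truth["fold_change"] < 1, "feature_id"])

    matrices = {}
    if compute_matrices:
        gene_ids = sorted(de_truth["feature_id"])
        for sample, cl in classified.items():
            matrices[sample] = metagene.metagene_matrix(
                annotation, cl, cfg, class_filter=de_class, gene_ids=gene_ids
            )

    return StudyResult(
        genome=genome,
        annotation=annotation,
        truth=truth,
        truth_table=truth_table,
        cfg=cfg,
        preprocess_stats=stats,
        classified=classified,
        counts=counts,
        unclassified=unclassified,
        size_factors=s,
        ma_table=ma_table,
        up=up,
        down=down,
        truth_up=truth_up,
        truth_down=truth_down,
        matrices=matrices,
    )


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
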