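"""Two-condition small-RNA read simulator with known ground truth.

Reads are generated so that their length, 5' nucleotide and strand encode
their class identity exactly as the downstream classifier expects:

* structural — 18-30 nt, sense over rRNA/tRNA/snRNA/snoRNA loci
* miRNA      — 21-24 nt, sense over mature-miRNA loci
* 21U        — 21 nt, 5' T, sense over piRNA (21ur) loci
* 22G / 26G  — 22 / 26 nt, 5' G, antisense to transposons or to exons of
               protein-coding genes, lincRNAs and pseudogenes

The 5' end of each antisense read is placed at a transcript-fraction
position drawn from a per-gene Beta(a, b), which realizes a tunable 5'
positional bias (small Beta mean -> coverage piled toward the TSS).
Per-replicate read counts are negative-binomial around the expected count
(times the fold change in the mutant). The forced 5' nucleotide of 21U and
22G/26G reads replaces the genomic base and is recorded as the read's one
allowed alignment mismatch.

The raw library layout emulates 4N adapters: four random bases on each
side of the insert followed by the 3' adapter, so the preprocessing rules
(adapter trim, 26-38 nt size window, 4-base flank strip) can be exercised
end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    GENIC_TARGET_BIOTYPES,
    STRUCTURAL_BIOTYPES,
    FeatureRecord,
    GenomeAnnotation,
)
from .config import DEFAULT_ADAPTER_3P
from .genome import ToyGenome, reverse_complement

CLASSES = ("structural", "miRNA", "21U", "22G", "26G")
_CLASS_OF_BIOTYPE = {
    **{bt: "structural" for bt in STRUCTURAL_BIOTYPES},
    "miRNA_mature": "miRNA",
    "piRNA_21ur": "21U",
}
_RESAMPLE_CAP = 200


@dataclass
class FeatureTruth:
    """Per-feature simulation parameters."""

    feature_id: str
    biotype: str
    sclass: str  # intended small-RNA class of reads from this feature
    expected_count: float  # per-replicate wild-type mean
    fold_change: float = 1.0  # mutant multiplier
    beta_wt: tuple[float, float] = (1.0, 1.0)
    beta_mut: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.expected_count < 0:
            raise ValueError("expected_count must be nonnegative")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be strictly positive")
        for a, b in (self.beta_wt, self.beta_mut):
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be strictly positive")


@dataclass
class SimulationTruth:
    features: list[FeatureTruth]
    class_mix: dict[str, float]
    n_replicates: int = 3
    dispersion: float = 0.05  # NB overdispersion; 0 -> Poisson
    seed: int = 0
    conditions: tuple[str, str] = ("wt", "mutant")

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [f.feature_id for f in self.features],
                "biotype": [f.biotype for f in self.features],
                "class": [f.sclass for f in self.features],
                "expected_count": [f.expected_count for f in self.features],
                "fold_change": [f.fold_change for f in self.features],
                "beta_a_wt": [f.beta_wt[0] for f in self.features],
                "beta_b_wt": [f.beta_wt[1] for f in self.features],
                "beta_a_mut": [f.beta_mut[0] for f in self.features],
                "beta_b_mut": [f.beta_mut[1] for f in self.features],
            }
        )


def make_truth(
    annotation: GenomeAnnotation,
    class_mix: dict[str, float],
    reads_per_sample: int,
    n_replicates: int = 3,
    dispersion: float = 0.05,
    frac_26g: float = 0.0,
    frac_up: float = 0.0,
    frac_down: float = 0.0,
    fold_up: float = 4.0,
    fold_down: float = 0.25,
    beta_wt: tuple[float, float] = (1.0, 1.0),
    beta_mut: tuple[float, float] | None = None,
    seed: int = 0,
) -> SimulationTruth:
    """Distribute the class mix over annotated features.

    Target-biotype features (protein_coding/lincRNA/pseudogene/transposon)
    host 22G reads, with a `frac_26g` share reassigned to 26G. Expected
    counts within a class follow log-normal weights; a `frac_up`/`frac_down`
    share of 22G/26G features receives the mutant fold change. The mutant
    Beta parameters default to the wild-type ones (no positional effect).
    """
    rng = np.random.default_rng(seed)
    if beta_mut is None:
        beta_mut = beta_wt
    by_class: dict[str, list[FeatureRecord]] = {c: [] for c in CLASSES}
    for f in annotation.features:
        cls = _CLASS_OF_BIOTYPE.get(f.biotype)
        if cls is None:  # 22G/26G target space
            cls = "22G"
        by_class[cls].append(f)
    n22 = len(by_class["22G"])
    if frac_26g > 0 and n22:
        k = int(round(frac_26g * n22))
        idx = rng.choice(n22, size=k, replace=False)
        moved = [by_class["22G"][i] for i in sorted(idx)]
        by_class["22G"] = [f for f in by_class["22G"] if f not in moved]
        by_class["26G"].extend(moved)

    truths: list[FeatureTruth] = []
    for cls in CLASSES:
        mix = class_mix.get(cls, 0.0)
        feats = by_class[cls]
        if mix <= 0 or not feats:
            continue
        w = rng.lognormal(0.0, 0.5, size=len(feats))
        w /= w.sum()
        n_de = 0
        de_flags = np.zeros(len(feats), dtype=int)
        if cls in ("22G", "26G") and (frac_up or frac_down):
            nu = int(round(frac_up * len(feats)))
            nd = int(round(frac_down * len(feats)))
            picks = rng.choice(len(feats), size=min(nu + nd, len(feats)), replace=False)
            de_flags[picks[:nu]] = 1
            de_flags[picks[nu : nu + nd]] = -1
        for f, wi, flag in zip(feats, w, de_flags):
            fc = fold_up if flag == 1 else fold_down if flag == -1 else 1.0
            truths.append(
                FeatureTruth(
                    f.feature_id, f.biotype, cls,
                    expected_count=mix * reads_per_sample * wi,
                    fold_change=fc,
                    beta_wt=beta_wt,
                    beta_mut=beta_mut if cls in ("22G", "26G") else beta_wt,
                )
            )
    present = {t.sclass for t in truths}
    mix = {c: p for c, p in class_mix.items() if c in present}
    tot = sum(mix.values())
    mix = {c: p / tot for c, p in mix.items()}
    return SimulationTruth(
        truths, mix, n_replicates=n_replicates, dispersion=dispersion, seed=seed
    )


# ---------------------------------------------------------------------------
# read generation


def _spliced(genome: ToyGenome, f: FeatureRecord) -> str:
    seq = "".join(genome[f.chrom][s:e] for s, e in f.exons)
    return reverse_complement(seq) if f.strand == "-" else seq


def _nb_draw(rng, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mean)))


def _sense_read_origin(f: FeatureRecord, t5: int, length: int):
    """Genomic (start, strand) of a sense read whose 5' end sits at
    transcript coordinate t5. Single-exon geometry (may run past the 3'
    locus end for short loci such as mature miRNAs)."""
    if f.strand == "+":
        g = f.start + t5
        return g, "+"
    g = f.end - t5 - length
    return g, "-"


def _antisense_read_origin(f: FeatureRecord, t5: int, length: int):
    """Genomic (start, strand) of an antisense read whose 5' end maps to
    transcript coordinate t5; the read body extends toward the TSS."""
    if f.strand == "+":
        return f.start + t5 - length + 1, "-"
    return f.end - 1 - t5, "+"


class SimulationError(RuntimeError):
    pass


def simulate_reads(
    genome: ToyGenome,
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
    library_layout: str = "insert",
    adapter_3p: str = DEFAULT_ADAPTER_3P,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Generate reads for every (condition, replicate) sample.

    Returns ``(reads_by_sample, truth_table)`` where ``reads_by_sample``
    maps sample names (``wt1..``, ``mutant1..``) to ``(read_id, sequence)``
    pairs — the raw 4N-flanked, adapter-carrying sequence for layout
    ``raw``, or the bare insert for layout ``insert`` — and
    ``truth_table`` is one row per read with its intended class, insert
    and genomic origin.
    """
    if library_layout not in ("raw", "insert"):
        raise ValueError("library_layout must be 'raw' or 'insert'")
    bases = np.array(list("ACGT"))
    spliced_cache = {f.feature_id: _spliced(genome, annotation.by_id[f.feature_id])
                     for f in (annotation.by_id[t.feature_id] for t in truth.features)}

    reads: dict[str, list[tuple[str, str]]] = {}
    rows: list[dict] = []
    for cond_i, cond in enumerate(truth.conditions):
        is_mut = cond_i == 1
        for rep in range(truth.n_replicates):
            sample = f"{cond}{rep + 1}"
            out = reads.setdefault(sample, [])
            for fidx, ft in enumerate(truth.features):
                feat = annotation.by_id[ft.feature_id]
                mean = ft.expected_count * (ft.fold_change if is_mut else 1.0)
                # the count substream is keyed on (seed, replicate, feature)
                # but NOT the condition: under a null fold change the two
                # conditions share the same draw, so the only difference
                # between conditions is the one the truth encodes
                rng_n = np.random.default_rng([truth.seed, 7, rep, fidx])
                n = _nb_draw(rng_n, mean, truth.dispersion)
                rng = np.random.default_rng([truth.seed, 11, cond_i, rep, fidx])
                a, b = ft.beta_mut if is_mut else ft.beta_wt
                for i in range(n):
                    rec = _one_read(
                        rng, genome, feat, ft.sclass, a, b, spliced_cache[ft.feature_id]
                    )
                    read_id = f"{sample}:{ft.feature_id}:{i}"
                    insert = rec["insert"]
                    if library_layout == "raw":
                        flanks = "".join(rng.choice(bases, size=8))
                        seq = flanks[:4] + insert + flanks[4:] + adapter_3p
                    else:
                        seq = insert
                    out.append((read_id, seq))
                    rows.append(
                        {
                            "read_id": read_id,
                            "feature_id": ft.feature_id,
                            "class": ft.sclass,
                            "insert": insert,
                            "chrom": feat.chrom,
                            "start": rec["start"],
                            "strand": rec["strand"],
                            "condition": cond,
                            "replicate": rep + 1,
                            "mismatches": rec["mismatches"],
                        }
                    )
    cols = ["read_id", "feature_id", "class", "insert", "chrom", "start",
            "strand", "condition", "replicate", "mismatches"]
    table = pd.DataFrame(rows, columns=cols)
    return reads, table


def _one_read(rng, genome, feat, sclass, a, b, spliced):
    L = feat.exonic_length
    if sclass == "21U":
        length, t5, antis, force = 21, 0, False, "T"
    elif sclass == "miRNA":
        length, t5, antis, force = int(rng.integers(21, 25)), 0, False, None
    elif sclass == "structural":
        length = int(rng.integers(18, 31))
        length = min(length, L)
        t5 = int(rng.integers(0, L - length + 1))
        antis, force = False, None
    elif sclass in ("22G", "26G"):
        length = 22 if sclass == "22G" else 26
        antis, force = True, "G"
        t5 = None
        for _ in range(_RESAMPLE_CAP):
            frac = rng.beta(a, b)
            cand = int(frac * L)
            if cand >= length - 1 and cand < L:
                t5 = cand
                break
        if t5 is None:
            raise SimulationError(
                f"could not place a {sclass} read on {feat.feature_id} "
                f"(length {L}) within the resample cap"
            )
    else:
        raise ValueError(f"unknown class {sclass}")

    if antis:
        insert = reverse_complement(spliced[t5 - length + 1 : t5 + 1])
        gstart, gstrand = _antisense_read_origin(feat, t5, length)
    else:
        if t5 + length <= L:
            insert = spliced[t5 : t5 + length]
        else:  # short locus: extend past the 3' end on the genome
            if feat.strand == "+":
                gseq = genome[feat.chrom][feat.start + t5 : feat.start + t5 + length]
                insert = gseq
            else:
                gseq = genome[feat.chrom][feat.end - t5 - length : feat.end - t5]
                insert = reverse_complement(gseq)
        gstart, gstrand = _sense_read_origin(feat, t5, length)

    mismatches = 0
    if force is not None and insert[0] != force:
        insert = force + insert[1:]
        mismatches = 1
    return {"insert": insert, "start": gstart, "strand": gstrand,
            "mismatches": mismatches}


def write_fastq(path: str | Path, reads: list[tuple[str, str]]) -> None:
    """Phred+33 FASTQ with constant quality 'I'."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# count-level generator (for differential-test calibration)


def simulate_count_matrix(
    n_features: int = 500,
    n_reps: tuple[int, int] = (4, 4),
    frac_de: float = 0.10,
    fold_change: float = 4.0,
    dispersion: float = 0.05,
    mean_log: float = np.log(200.0),
    mean_sd: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Negative-binomial count matrix for a two-condition design.

    Per-feature base means are log-normal (median ~200 counts by default).
    A `frac_de` share of features is up-regulated `fold_change`-fold in the
    second condition. Returns (counts, condition labels, true-DE mask).
    """
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(mean_log, mean_sd, size=n_features)
    de = np.zeros(n_features, dtype=bool)
    de[rng.choice(n_features, size=int(round(frac_de * n_features)), replace=False)] = True
    n_wt, n_mut = n_reps
    cols, data = [], []
    for j in range(n_wt):
        cols.append(f"wt{j + 1}")
        data.append([_nb_draw(rng, m, dispersion) for m in mu])
    for j in range(n_mut):
        cols.append(f"mutant{j + 1}")
        data.append(
            [_nb_draw(rng, m * (fold_change if d else 1.0), dispersion)
             for m, d in zip(mu, de)]
        )
    counts = pd.DataFrame(
        np.column_stack(data),
        index=[f"g{i:04d}" for i in range(n_features)],
        columns=cols,
    )
    condition = pd.Series(
        ["wt"] * n_wt + ["mutant"] * n_mut, index=cols, name="condition"
    )
    return counts, condition, de
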