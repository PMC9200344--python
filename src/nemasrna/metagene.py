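"""Metagene coverage profiles and the 5'-shift statistic.

Each gene's exon-concatenated transcript is divided into 100 bins from
5'-TSS to 3'-TES; the bin value is the mean per-base read coverage in
its slice, so genes of different lengths become comparable. Two profile
flavours are computed over a genes x bins matrix:

* relative — rows with total coverage <= 10 are dropped (strictly
  greater than 10 kept), each remaining row is divided by its row sum,
  and the profile is the column sum. Every gene then contributes equal
  weight, which makes positional redistribution visible independently of
  expression level.
* total — the plain column sum divided by the sample's size factor; no
  filtering or per-gene normalization, so the profile is dominated by
  genes with strong small-RNA levels.

The centroid of a profile (weighted mean bin index) summarizes where
coverage mass sits along the transcript; the shift statistic
centroid(mutant) - centroid(wild type) is negative when coverage moves
toward the 5' end, the readout of interest for 22G-RNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import FeatureRecord, GenomeAnnotation
from .config import PipelineConfig


class EmptyProfileError(ValueError):
    pass


@dataclass
class MetageneProfile:
    values: np.ndarray  # n_bins, 5'->3'
    mode: str  # "relative" | "total"
    genes_used: int

    def centroid(self) -> float:
        return coverage_centroid(self.values)


def transcript_coverage(
    feature: FeatureRecord, reads, flag_short: bool = False
) -> np.ndarray:
    """Per-base coverage along the concatenated-exon transcript, 5'->3'.

    Read spans are intersected with the exons; intronic bases of a read
    contribute nothing. Orientation follows the feature strand, so index
    0 is always the TSS.
    """
    L = feature.exonic_length
    cov = np.zeros(L)
    offset = 0
    for s, e in feature.exons:
        for c in reads:
            read = getattr(c, "read", c)
            if read.chrom != feature.chrom:
                continue
            lo = max(read.start, s)
            hi = min(read.end, e)
            if lo < hi:
                cov[offset + (lo - s) : offset + (hi - s)] += 1.0
        offset += e - s
    if feature.strand == "-":
        cov = cov[::-1]
    return cov


def bin_vector(cov: np.ndarray, n_bins: int = 100) -> np.ndarray:
    """Mean per-base coverage in each of `n_bins` equal transcript slices.

    Bin b (1-based) covers the half-open slice [floor((b-1)L/B),
    floor(bL/B)); slices shorter than one base (gene shorter than the
    bin count) get value 0.
    """
    L = cov.size
    edges = (np.arange(n_bins + 1) * L) // n_bins
    out = np.zeros(n_bins)
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        if hi > lo:
            out[b] = cov[lo:hi].mean()
    return out


def bin_coverage(
    feature: FeatureRecord, reads, cfg: PipelineConfig | None = None
) -> np.ndarray:
    cfg = cfg or PipelineConfig()
    if feature.exonic_length == 0:
        raise ValueError(f"feature {feature.feature_id} has zero exonic length")
    return bin_vector(transcript_coverage(feature, reads), cfg.n_bins)


def metagene_matrix(
    annotation: GenomeAnnotation,
    classified,
    cfg: PipelineConfig | None = None,
    class_filter: str | None = "22G",
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Genes x bins coverage matrix for one sample and one read class."""
    cfg = cfg or PipelineConfig()
    by_feature: dict[str, list] = {}
    for c in classified:
        if class_filter is not None and c.sclass != class_filter:
            continue
        if c.feature_id is not None:
            by_feature.setdefault(c.feature_id, []).append(c)
    ids = gene_ids if gene_ids is not None else sorted(by_feature)
    rows = []
    for fid in ids:
        feat = annotation.by_id[fid]
        rows.append(bin_coverage(feat, by_feature.get(fid, []), cfg))
    return pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, cfg.n_bins)),
        index=ids,
        columns=[f"bin{b}" for b in range(1, cfg.n_bins + 1)],
    )


def relative_profile(
    M: pd.DataFrame, cfg: PipelineConfig | None = None
) -> MetageneProfile:
    """Row-filter (row sums strictly above `rowsum_min`), per-gene row
    normalization, then column sums."""
    cfg = cfg or PipelineConfig()
    if M.shape[1] != cfg.n_bins:
        raise ValueError(f"matrix has {M.shape[1]} bins, config says {cfg.n_bins}")
    sums = M.sum(axis=1)
    kept = M.loc[sums > cfg.rowsum_min]
    if kept.empty:
        raise EmptyProfileError("no gene passes the row-sum filter")
    norm = kept.div(kept.sum(axis=1), axis=0)
    return MetageneProfile(norm.sum(axis=0).to_numpy(), "relative", len(kept))


def total_profile(M: pd.DataFrame, size_factor: float) -> MetageneProfile:
    """Column sums divided by the sample's size factor; no row filtering
    or per-gene normalization."""
    if not np.isfinite(size_factor) or size_factor <= 0:
        raise ValueError("size factor must be a positive real")
    return MetageneProfile(M.sum(axis=0).to_numpy() / size_factor, "total", len(M))


def coverage_centroid(values: np.ndarray) -> float:
    """Weighted mean bin index (1-based): sum_b b*v_b / sum_b v_b."""
    v = np.asarray(values, dtype=float)
    total = v.sum()
    if total <= 0:
        raise EmptyProfileError("centroid undefined for a zero-sum vector")
    bins = np.arange(1, v.size + 1)
    return float((bins * v).sum() / total)


def centroid_shift(profile_mut: MetageneProfile, profile_wt: MetageneProfile) -> float:
    """centroid(mutant) - centroid(wild type); negative = 5' shift."""
    return profile_mut.centroid() - profile_wt.centroid()


def profile_by_geneset(
    M: pd.DataFrame,
    gene_ids,
    mode: str = "relative",
    cfg: PipelineConfig | None = None,
    size_factor: float | None = None,
) -> MetageneProfile:
    """Profile restricted to the intersection of the matrix with a gene set."""
    ids = [g for g in M.index if g in set(gene_ids)]
    if not ids:
        raise EmptyProfileError("gene set does not intersect the matrix")
    sub = M.loc[ids]
    if mode == "relative":
        return relative_profile(sub, cfg)
    if mode == "total":
        if size_factor is None:
            raise ValueError("total mode requires a size factor")
        return total_profile(sub, size_factor)
    raise ValueError(f"unknown mode {mode!r}")


def unaffected_set(
    ma_table: pd.DataFrame, base_mean_min: float = 10.0, use_adjusted: bool = False
) -> set[str]:
    """Genes with no detectable change: p = 1 (raw by default, adjusted
    optionally) and baseMean above `base_mean_min`."""
    p = ma_table["padj"] if use_adjusted else ma_table["pvalue"]
    keep = (p >= 1.0) & (ma_table["baseMean"] > base_mean_min)
    return set(ma_table.index[keep])
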