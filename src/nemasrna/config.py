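"""Pipeline-wide configuration.

All printed thresholds of the analysis live here: the 3' adapter, the
26-38 nt post-trim window (18-30 nt inserts plus 8 random adapter bases),
the 4-base random flanks, the one-mismatch alignment policy, the 100-bin
metagene geometry, the strict rowSums > 10 metagene filter, and the
2-fold / 10%-FDR deregulation cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: NEXTflex-style small-RNA 3' adapter.
DEFAULT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class PipelineConfig:
    adapter_3p: str = DEFAULT_ADAPTER_3P
    post_trim_min: int = 26
    post_trim_max: int = 38
    flank_trim: int = 4
    max_mismatches: int = 1
    n_bins: int = 100
    rowsum_min: float = 10.0  # exclusive: rows must sum to strictly more
    fc_cutoff: float = 2.0
    fdr_level: float = 0.10
    seed: int = 0
    #: exact-seed length of the toy aligner index; must be at most half the
    #: shortest insert so the pigeonhole split guarantees one mismatch-free seed
    index_k: int = 9
    #: keep reads flagged as multimappers (counted once at the reported
    #: position) or drop them before classification
    keep_multimappers: bool = True
    #: admit 26G reads antisense to transposons (not only gene exons)
    allow_26g_transposons: bool = True
    adapter_min_prefix: int = 3
    adapter_max_error_rate: float = 0.10

    def __post_init__(self) -> None:
        if not self.adapter_3p:
            raise ValueError("adapter_3p must be non-empty")
        if self.post_trim_min > self.post_trim_max:
            raise ValueError("post_trim_min must be <= post_trim_max")
        if self.flank_trim < 0:
            raise ValueError("flank_trim must be >= 0")
        if not (0.0 < self.fdr_level < 1.0):
            raise ValueError("fdr_level must lie in (0, 1)")
        if self.fc_cutoff <= 1.0:
            raise ValueError("fc_cutoff must exceed 1")

    @property
    def insert_min(self) -> int:
        return self.post_trim_min - 2 * self.flank_trim

    @property
    def insert_max(self) -> int:
        return self.post_trim_max - 2 * self.flank_trim
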