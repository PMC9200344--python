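"""Adapter trimming, insert size selection and random-flank removal.

Small-RNA inserts (18-30 nt) are shorter than the sequenced read, so each
read carries: 4 random bases + insert + 4 random bases + 3' adapter. The
cleaning rules are: truncate at the leftmost adapter match (full match
anywhere, or an adapter prefix of >= 3 bases at the read's 3' end, with
<= 10% mismatches in the matched region), keep reads whose post-trim
length lies in [26, 38] (insert 18-30 nt plus the 8 random bases), then
strip 4 bases from each end to recover the insert. Reads without an
adapter match are rejected — the insert boundary cannot be confirmed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import PipelineConfig

REJECT_REASONS = ("empty", "no_adapter", "too_short", "too_long", "short_after_flank")


@dataclass
class TrimmedRead:
    read_id: str
    sequence: str


@dataclass
class RejectedRead:
    read_id: str
    reason: str


def _adapter_match_at(seq: str, pos: int, adapter: str, min_prefix: int,
                      max_error_rate: float) -> bool:
    """Adapter (or its 3'-terminal prefix) matches seq starting at pos?"""
    avail = len(seq) - pos
    mlen = min(avail, len(adapter))
    if mlen < len(adapter) and mlen < min_prefix:
        return False
    if mlen <= 0:
        return False
    allowed = int(max_error_rate * mlen)
    mism = 0
    for a, b in zip(seq[pos : pos + mlen], adapter[:mlen]):
        if a != b:
            mism += 1
            if mism > allowed:
                return False
    return True


def find_adapter(seq: str, cfg: PipelineConfig) -> int | None:
    """0-based position of the leftmost adapter match, or None.

    Fast path: exact full-adapter substring search; otherwise a scan
    allowing <= cfg.adapter_max_error_rate mismatches in the matched
    region, accepting a terminal adapter prefix of >= cfg.adapter_min_prefix.
    """
    exact = seq.find(cfg.adapter_3p)
    scan_end = exact if exact >= 0 else len(seq)
    for pos in range(scan_end):
        if _adapter_match_at(seq, pos, cfg.adapter_3p, cfg.adapter_min_prefix,
                             cfg.adapter_max_error_rate):
            return pos
    return exact if exact >= 0 else None


def trim_adapter(read_id: str, sequence: str, cfg: PipelineConfig):
    """Trim at the leftmost adapter match and apply the size window.

    Returns a TrimmedRead or a RejectedRead with reason in
    {empty, no_adapter, too_short, too_long}.
    """
    if not sequence:
        return RejectedRead(read_id, "empty")
    pos = find_adapter(sequence, cfg)
    if pos is None:
        return RejectedRead(read_id, "no_adapter")
    trimmed = sequence[:pos]
    if len(trimmed) < cfg.post_trim_min:
        return RejectedRead(read_id, "too_short")
    if len(trimmed) > cfg.post_trim_max:
        return RejectedRead(read_id, "too_long")
    return TrimmedRead(read_id, trimmed)


def strip_flanks(read: TrimmedRead, cfg: PipelineConfig):
    """Remove the 4 random bases from each end, leaving the insert."""
    k = cfg.flank_trim
    if len(read.sequence) < 2 * k + 1:
        return RejectedRead(read.read_id, "short_after_flank")
    return TrimmedRead(read.read_id, read.sequence[k : len(read.sequence) - k])


def preprocess_reads(
    reads: list[tuple[str, str]], cfg: PipelineConfig
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Run trim + size-select + flank-strip over a read set.

    Returns (kept (read_id, insert) pairs, per-read log with category).
    """
    kept: list[tuple[str, str]] = []
    log_rows = []
    for read_id, seq in reads:
        res = trim_adapter(read_id, seq, cfg)
        if isinstance(res, TrimmedRead):
            res = strip_flanks(res, cfg)
        if isinstance(res, TrimmedRead):
            kept.append((read_id, res.sequence))
            log_rows.append((read_id, "kept"))
        else:
            log_rows.append((read_id, res.reason))
    log = pd.DataFrame(log_rows, columns=["read_id", "category"])
    return kept, log


def preprocess_stats(log: pd.DataFrame) -> pd.DataFrame:
    """Summary table whose categories partition the input reads."""
    cats = ["kept", *REJECT_REASONS]
    counts = log["category"].value_counts() if len(log) else pd.Series(dtype=int)
    table = pd.DataFrame(
        {"category": cats, "n_reads": [int(counts.get(c, 0)) for c in cats]}
    )
    table.loc[len(table)] = ("total", int(len(log)))
    return table


def write_rejection_log(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, sep="\t", index=False)
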