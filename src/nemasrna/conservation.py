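"""Normalized reciprocal-best-BLAST-hit conservation scores.

Given tabular BLASTP output (the 12-column `-outfmt 6` layout) for a
forward search (reference proteome as query against each species) and
the reciprocal search (each species' proteome against the reference),
the score of a reference protein in species S is:

* the best forward hit h of the reference protein in S is looked up;
* if the best reciprocal hit of h is the reference protein again, the
  score is the reciprocal bit score divided by the reference protein's
  self bit score;
* otherwise (no forward hit, or reciprocity fails) the score is 0.

The reference species against itself scores exactly 1. Scores can
exceed 1 when a reciprocal bit score beats the self score; they are
reported unclipped and flagged. Duplicate (query, subject) hit lines
keep only the maximal bit score, so re-fed files change nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

#: classic BLAST tabular columns (-outfmt 6)
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Load a 12-column tabular BLAST file, keeping the maximal bit score
    per (query, subject) pair."""
    hits = pd.read_csv(
        path, sep="\t", header=None, names=OUTFMT6_COLUMNS, comment="#"
    )
    if (hits["bitscore"] < 0).any():
        raise ValueError(f"{path}: negative bit score")
    return (
        hits.sort_values("bitscore", ascending=False)
        .drop_duplicates(["qseqid", "sseqid"], keep="first")
        .reset_index(drop=True)
    )


def best_hit(hits: pd.DataFrame, query_id: str) -> tuple[str, float] | None:
    """Subject with the maximal bit score for the query; ties broken by
    lexicographic subject id. None when the query has no hits."""
    sub = hits.loc[hits["qseqid"] == query_id]
    if sub.empty:
        return None
    top = sub.loc[sub["bitscore"] == sub["bitscore"].max()]
    row = top.sort_values("sseqid").iloc[0]
    return str(row["sseqid"]), float(row["bitscore"])


def rbh_score(
    forward: pd.DataFrame,
    reverse: pd.DataFrame,
    reference_id: str,
    self_bit_score: float,
) -> float:
    """Normalized reciprocal-best-hit score for one species."""
    if self_bit_score <= 0:
        raise ValueError("self bit score must be positive")
    fwd = best_hit(forward, reference_id)
    if fwd is None:
        return 0.0
    subject, _fwd_bits = fwd
    rev = best_hit(reverse, subject)
    if rev is None or rev[0] != reference_id:
        return 0.0
    return rev[1] / self_bit_score


def self_bit_score_from_hits(hits: pd.DataFrame, reference_id: str) -> float:
    """Bit score of the reference protein against itself, taken from a
    self-proteome search file."""
    row = hits.loc[
        (hits["qseqid"] == reference_id) & (hits["sseqid"] == reference_id)
    ]
    if row.empty:
        raise ValueError(f"no self hit for {reference_id}")
    return float(row["bitscore"].max())


@dataclass
class SpeciesHits:
    species: str
    forward: pd.DataFrame  # reference proteome vs this species
    reverse: pd.DataFrame  # this species vs reference proteome


def score_matrix(
    species_hits: list[SpeciesHits],
    reference_ids: list[str],
    self_bit_scores: dict[str, float],
) -> pd.DataFrame:
    """Reference proteins x species matrix of normalized RBH scores.

    Species column order follows the input manifest order; duplicate
    species labels are rejected.
    """
    labels = [sh.species for sh in species_hits]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species labels in manifest")
    data = {
        sh.species: [
            rbh_score(sh.forward, sh.reverse, ref, self_bit_scores[ref])
            for ref in reference_ids
        ]
        for sh in species_hits
    }
    return pd.DataFrame(data, index=reference_ids, columns=labels)


def score_matrix_long(matrix: pd.DataFrame) -> pd.DataFrame:
    long = matrix.reset_index(names="protein").melt(
        id_vars="protein", var_name="species", value_name="score"
    )
    long["exceeds_self"] = long["score"] > 1.0
    return long


def load_manifest(path: str | Path) -> list[SpeciesHits]:
    """Manifest TSV: species label, forward hits file, reverse hits file.

    Paths are resolved relative to the manifest location.
    """
    base = Path(path).parent
    man = pd.read_csv(path, sep="\t", header=None,
                      names=["species", "forward", "reverse"])
    return [
        SpeciesHits(
            row["species"],
            read_blast_tab(base / row["forward"]),
            read_blast_tab(base / row["reverse"]),
        )
        for _, row in man.iterrows()
    ]
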