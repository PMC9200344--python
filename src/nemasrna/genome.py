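"""Toy genome generation and FASTA I/O.

The toy genome stands in for a real assembly at desk scale: i.i.d.
nucleotides with a configurable GC fraction, reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pyfaidx import Fasta

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ToyGenome:
    chrom_names: list[str]
    sequences: dict[str, str]
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            seq = self.sequences[name]
            if not seq:
                raise ValueError(f"chromosome {name} is empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name} contains non-ACGT bases")

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.chrom_names:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ToyGenome":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        names = list(fa.keys())
        return cls(chrom_names=names, sequences={n: str(fa[n][:]) for n in names})


def generate_genome(
    n_chrom: int,
    chrom_length: int,
    gc_fraction: float = 0.36,
    seed: int = 0,
) -> ToyGenome:
    """Draw a random genome of `n_chrom` chromosomes of `chrom_length` bases.

    Nucleotides are i.i.d. with P(G) = P(C) = gc_fraction / 2. The same
    seed reproduces the same genome byte for byte.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1000")
    if not (0.0 < gc_fraction < 1.0):
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    names = [f"chrI_{i + 1}" if n_chrom > 1 else "chrI" for i in range(n_chrom)]
    sequences = {}
    for name in names:
        draws = rng.choice(alphabet, size=chrom_length, p=[at, gc, gc, at])
        sequences[name] = draws.tobytes().decode("ascii")
    return ToyGenome(chrom_names=names, sequences=sequences, seed=seed)
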