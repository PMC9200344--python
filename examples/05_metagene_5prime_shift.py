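"""Metagene profiles and the 5' shift of 22G-RNA coverage.

Genes are rescaled to 100 bins from TSS to TES. The wild type places
22G-RNA 5' ends symmetrically (Beta(2,2), mean fraction 0.5); the mutant
is 5'-skewed (Beta(1.2,2.8), mean 0.3). In the relative profile each
kept gene (row sum > 10) contributes equal weight, and the centroid
(weighted mean bin) drops from ~50 to ~30.
"""

import numpy as np
import pandas as pd

from nemasrna import PipelineConfig
from nemasrna.align import AlignedRead
from nemasrna.annotation import generate_annotation
from nemasrna.genome import generate_genome
from nemasrna.metagene import bin_coverage, coverage_centroid, relative_profile
from nemasrna.simulate import make_truth, simulate_reads

cfg = PipelineConfig()
genome = generate_genome(1, 200_000, 0.36, seed=0)
annotation = generate_annotation(genome, {"protein_coding": 80}, seed=1)
truth = make_truth(
    annotation, {"22G": 1.0}, 8_000, n_replicates=1, dispersion=0.0,
    beta_wt=(2.0, 2.0), beta_mut=(1.2, 2.8), seed=2,
)
_, table = simulate_reads(genome, annotation, truth, "insert")

profiles = {}
for cond in ("wt", "mutant"):
    sub = table[table["condition"] == cond]
    rows = {}
    for fid, grp in sub.groupby("feature_id"):
        feat = annotation.by_id[fid]
        reads = [AlignedRead(str(i), "G" * 22, feat.chrom, int(s), "-", 0)
                 for i, s in enumerate(grp["start"])]
        rows[fid] = bin_coverage(feat, reads, cfg)
    M = pd.DataFrame(rows).T
    M.columns = [f"bin{b}" for b in range(1, 101)]
    profiles[cond] = relative_profile(M, cfg)

for cond, prof in profiles.items():
    print(f"{cond:7s}: {prof.genes_used} genes kept, "
          f"centroid bin {prof.centroid():.1f}")
shift = profiles["mutant"].centroid() - profiles["wt"].centroid()
print(f"\ncentroid shift (mutant - wt): {shift:.1f} bins")
print("A negative shift of ~20 bins means 22G-RNA coverage has moved toward "
      "the transcript 5' end,\nthe hallmark readout over WAGO/mutator targets.")
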