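"""Call deregulated 22G-RNA loci between wild type and mutant.

Median-of-ratios size factors normalize library depth; a moderated
negative-binomial Wald test gives per-locus p-values; calls require
BH-adjusted q <= 0.10 and at least a 2-fold change.
"""

from nemasrna.pipeline import jaccard, run_toy_study

study = run_toy_study(seed=0, reads_per_sample=10_000)

print("size factors (22G table):")
print(study.size_factors.round(3).to_string())

ma = study.ma_table
print(f"\n{len(ma)} loci tested; "
      f"{(ma['call'] == 'up').sum()} up, {(ma['call'] == 'down').sum()} down "
      "at >=2-fold / 10% FDR")
print("\ntop up-regulated loci:")
cols = ["baseMean", "log2FoldChange", "padj", "call"]
print(ma[ma["call"] == "up"].nsmallest(3, "padj")[cols].round(3).to_string())

print(f"\ntruth recovery: Jaccard(up) = {jaccard(study.up, study.truth_up):.2f}, "
      f"Jaccard(down) = {jaccard(study.down, study.truth_down):.2f}")
print("A Jaccard of 1.0 means the called gene sets equal the simulated "
      "4-fold-up and 4-fold-down sets exactly.")
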