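"""Median-of-ratios normalization, a negative-binomial Wald test,
Benjamini-Hochberg FDR control, 2-fold / 10%-FDR deregulation calls, and
size-factor-normalized bedGraph coverage tracks.

The differential test is a deliberately simple NB Wald test: per-feature
dispersion by method of moments on normalized counts (no shrinkage, no
GLM covariates), a pseudocount of 0.5 stabilizing fold changes at zero
counts, and a delta-method standard error for log2FC. The scheme that
matters downstream — median-of-ratios size factors and the ">= 2-fold at
10% FDR" thresholding — is implemented exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig

ALPHA_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


class NormalizationError(ValueError):
    pass


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    s_j = median over features g of c_gj / (prod_k c_gk)^(1/m), taken
    over features whose counts are positive in every sample (the
    geometric mean is otherwise zero). Invariant to feature order.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.min() < 0:
        raise ValueError("counts must be nonnegative")
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise NormalizationError(
            "no feature has positive counts in every sample; "
            "median-of-ratios is undefined"
        )
    ref = mat[all_pos]
    log_gm = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_gm)
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, s: pd.Series) -> pd.DataFrame:
    return counts.div(s, axis=1)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values:
    q_(i) = min_{j >= i} p_(j) * m / j, clipped to 1, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_test(
    counts: pd.DataFrame,
    s: pd.Series,
    condition: pd.Series,
    fixed_dispersion: float | None = None,
    dispersion_prior_df: float = 20.0,
) -> pd.DataFrame:
    """Two-condition NB Wald test on normalized counts.

    `condition` maps sample -> label; the first label in appearance
    order is the reference (wild type). Requires >= 2 replicates per
    condition unless `fixed_dispersion` is given. Per-gene dispersions
    are moderated toward the across-gene median (`dispersion_prior_df`
    pseudo-replicates of prior weight). Returns a frame with baseMean,
    log2FoldChange, pvalue and padj per feature.
    """
    condition = condition.loc[counts.columns]
    levels = list(dict.fromkeys(condition))
    if len(levels) != 2:
        raise ValueError(f"expected exactly two conditions, got {levels}")
    ref, alt = levels
    n_ref = int((condition == ref).sum())
    n_alt = int((condition == alt).sum())
    if fixed_dispersion is None and min(n_ref, n_alt) < 2:
        raise ValueError(
            "need >= 2 replicates per condition to estimate dispersion "
            "(or pass fixed_dispersion)"
        )
    y = normalized_counts(counts, s).to_numpy(dtype=float)
    mask_ref = (condition == ref).to_numpy()
    mask_alt = (condition == alt).to_numpy()
    y_ref, y_alt = y[:, mask_ref], y[:, mask_alt]
    m_ref = y_ref.mean(axis=1)
    m_alt = y_alt.mean(axis=1)
    base_mean = y.mean(axis=1)

    if fixed_dispersion is not None:
        alpha = np.full(len(y), max(fixed_dispersion, ALPHA_FLOOR))
    else:
        # method of moments: pooled within-condition variance vs pooled mean
        df = (n_ref - 1) + (n_alt - 1)
        ss = y_ref.var(axis=1, ddof=1) * (n_ref - 1) + y_alt.var(axis=1, ddof=1) * (
            n_alt - 1
        )
        pooled_var = ss / df
        pooled_mean = (m_ref * n_ref + m_alt * n_alt) / (n_ref + n_alt)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_raw = (pooled_var - pooled_mean) / pooled_mean**2
        alpha_raw = np.where(np.isfinite(alpha_raw), alpha_raw, 0.0)
        # per-gene moment estimates from a handful of replicates are far
        # too noisy on their own; as in the standard small-sample DE
        # tools, share information across genes by squeezing each
        # estimate toward the across-gene median with `dispersion_prior_df`
        # pseudo-degrees of freedom
        common = float(np.median(alpha_raw)) if len(alpha_raw) else 0.0
        alpha = (df * alpha_raw + dispersion_prior_df * common) / (
            df + dispersion_prior_df
        )
        alpha = np.maximum(alpha, ALPHA_FLOOR)

    log2fc = np.log2((m_alt + PSEUDOCOUNT) / (m_ref + PSEUDOCOUNT))
    # delta method on log2 of shifted means; Var(mean NB) = (mu + a mu^2)/n
    var_ref = (m_ref + alpha * m_ref**2) / n_ref
    var_alt = (m_alt + alpha * m_alt**2) / n_alt
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_alt / (m_alt + PSEUDOCOUNT) ** 2 + var_ref / (m_ref + PSEUDOCOUNT) ** 2
    ) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    # the dispersion (hence the standard error) is estimated from few
    # replicates; a Student-t reference with the pooled residual degrees
    # of freedom absorbs that extra noise. With a fixed dispersion the
    # error is not estimated and the normal reference applies.
    if fixed_dispersion is None:
        dof = (n_ref - 1) + (n_alt - 1) + dispersion_prior_df
        pvalue = 2.0 * stats.t.sf(np.abs(z), dof)
    else:
        pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.minimum(pvalue, 1.0)
    res = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
        },
        index=counts.index,
    )
    return res


def call_deregulated(
    res: pd.DataFrame, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """Annotate the MA table with up/down/ns calls at >=`fc_cutoff`-fold
    and `fdr_level` FDR (both inclusive)."""
    cfg = cfg or PipelineConfig()
    lfc_min = np.log2(cfg.fc_cutoff)
    sig = res["padj"] <= cfg.fdr_level
    call = np.where(
        sig & (res["log2FoldChange"] >= lfc_min),
        "up",
        np.where(sig & (res["log2FoldChange"] <= -lfc_min), "down", "ns"),
    )
    out = res.copy()
    out["call"] = call
    return out


def deregulated_sets(ma_table: pd.DataFrame) -> tuple[set[str], set[str]]:
    up = set(ma_table.index[ma_table["call"] == "up"])
    down = set(ma_table.index[ma_table["call"] == "down"])
    return up, down


# ---------------------------------------------------------------------------
# coverage tracks


def coverage_arrays(
    classified, chrom_lengths: dict[str, int], size_factor: float = 1.0
) -> dict[str, np.ndarray]:
    """Per-base read coverage divided by the sample's size factor."""
    cov = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    for c in classified:
        read = getattr(c, "read", c)
        arr = cov[read.chrom]
        arr[read.start : read.end] += 1.0
    if size_factor != 1.0:
        for arr in cov.values():
            arr /= size_factor
    return cov


def write_bedgraph(cov: dict[str, np.ndarray], path: str | Path) -> None:
    """Run-length-encoded bedGraph; zero-coverage runs are omitted."""
    with open(path, "w") as fh:
        for chrom in cov:
            arr = cov[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s0, e0 in zip(starts, ends):
                v = arr[s0]
                if v != 0:
                    fh.write(f"{chrom}\t{s0}\t{e0}\t{v:g}\n")


def normalized_coverage_tracks(
    classified_by_sample: dict[str, list],
    s: pd.Series,
    chrom_lengths: dict[str, int],
    outdir: str | Path,
    class_filter: str | None = "22G",
) -> dict[str, Path]:
    """One bedGraph per sample, per-base coverage divided by its size factor."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample, classified in classified_by_sample.items():
        if sample not in s.index:
            raise KeyError(f"no size factor for sample {sample}")
        reads = [
            c for c in classified if class_filter is None or c.sclass == class_filter
        ]
        cov = coverage_arrays(reads, chrom_lengths, float(s[sample]))
        path = outdir / f"{sample}.bedgraph"
        write_bedgraph(cov, path)
        paths[sample] = path
    return paths
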