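"""Gene-level expression from poly(A)-site counts and a SIMPLIFIED
negative-binomial differential-expression test.

The test is a deliberately reduced stand-in for a full NB GLM package:
median-of-ratios size factors, a single common method-of-moments dispersion,
and a Wald statistic on the log2 fold change against a normal reference. No
dispersion shrinkage, Cook's filtering, or independent filtering. Output
columns mirror the conventional layout (baseMean, log2FoldChange, lfcSE,
stat, pvalue, adj_pvalue).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from apakit._util import (
    CONTROL,
    TREATED,
    bh_adjust,
    check_design,
    condition_samples,
)

SIMPLIFIED_NOTE = "simplified-NB-Wald (not a full NB GLM implementation)"


def aggregate_gene_counts(site_table: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Sum site counts to gene x sample totals (exact integer sums)."""
    out = site_table.groupby("gene_id", sort=True)[samples].sum().reset_index()
    return out


def filter_low_expression(
    gene_counts: pd.DataFrame, samples: list[str], min_avg: float = 2.0
) -> pd.DataFrame:
    """Keep genes with mean count >= ``min_avg`` across ALL samples."""
    means = gene_counts[samples].mean(axis=1)
    return gene_counts[means >= min_avg].reset_index(drop=True)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios against the geometric-mean pseudo-reference.

    Genes whose geometric mean is zero are skipped in the per-sample median.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("sample with all-zero counts")
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    log_geomean = log_counts.mean(axis=1)
    ok = np.isfinite(log_geomean)
    if not ok.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = log_counts[ok] - log_geomean[ok, None]
    return np.exp(np.median(ratios, axis=0))


def nb_differential_expression(
    gene_counts: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Simplified NB Wald test per gene (see module docstring)."""
    check_design(design)
    samples = design["sample"].tolist()
    ctrl = condition_samples(design, CONTROL)
    trt = condition_samples(design, TREATED)
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need >= 2 samples per condition")
    counts = gene_counts[samples].to_numpy(dtype=float)
    sf = size_factors(counts)
    sf_by_sample = dict(zip(samples, sf))
    norm = counts / sf

    idx_c = [samples.index(s) for s in ctrl]
    idx_t = [samples.index(s) for s in trt]
    mu_c = norm[:, idx_c].mean(axis=1)
    mu_t = norm[:, idx_t].mean(axis=1)
    base_mean = norm.mean(axis=1)

    # common dispersion by pooled method of moments (ratio of sums is far
    # less biased than a median of noisy per-gene estimates at small n):
    # E[within-condition var of K/s] = mu * mean(1/s) + alpha * mu^2
    resid_var = (
        norm[:, idx_c].var(axis=1, ddof=1) * (len(idx_c) - 1)
        + norm[:, idx_t].var(axis=1, ddof=1) * (len(idx_t) - 1)
    ) / (len(samples) - 2)
    mu_all = (mu_c * len(idx_c) + mu_t * len(idx_t)) / len(samples)
    mean_inv_sf = float(np.mean(1.0 / sf))
    ok = mu_all > 0
    denom = float(np.sum(mu_all[ok] ** 2))
    alpha = (
        float(np.sum(resid_var[ok] - mu_all[ok] * mean_inv_sf)) / denom
        if denom > 0
        else 0.0
    )
    alpha = max(alpha, 1e-8)

    eps = 1e-8
    log2fc = np.log2(np.maximum(mu_t, eps) / np.maximum(mu_c, eps))

    def var_log2_mean(mu: np.ndarray, idx: list[int]) -> np.ndarray:
        # delta method: Var(K_j/s_j) = mu/s_j + alpha*mu^2 under the NB model
        mu_f = np.maximum(mu, eps)
        per_sample = mu_f[:, None] / sf[idx][None, :] + alpha * mu_f[:, None] ** 2
        var_mean = per_sample.sum(axis=1) / len(idx) ** 2
        return var_mean / (mu_f**2 * np.log(2.0) ** 2)

    v = var_log2_mean(mu_c, idx_c) + var_log2_mean(mu_t, idx_t)
    lfc_se = np.sqrt(np.maximum(v, 1e-300))
    stat = log2fc / lfc_se
    p = 2.0 * stats.norm.sf(np.abs(stat))

    out = pd.DataFrame(
        {
            "gene_id": gene_counts["gene_id"].to_numpy(),
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "lfcSE": lfc_se,
            "stat": stat,
            "pvalue": p,
            "adj_pvalue": bh_adjust(p),
        }
    )
    out.attrs["method"] = SIMPLIFIED_NOTE
    out.attrs["size_factors"] = sf_by_sample
    out.attrs["dispersion"] = alpha
    return out
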