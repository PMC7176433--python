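"""Weighted mRNA length score and shortening enrichment.

Per gene, each poly(A) site gets a weight decreasing linearly from 1 at the
most distal site to 0 at the most proximal; the per-sample length score is
the weight-weighted sum of site CPM values. The relative length change is
mean(treated score) - mean(control score); negative = shortening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from apakit._util import (
    CONTROL,
    TREATED,
    check_design,
    condition_samples,
    gof_chi2,
)


def site_weights(ns: int) -> np.ndarray:
    """W_i = 1 - (i - 1)/(NS - 1) for distal-first index i = 1..NS.

    A single-site gene gets the degenerate weight 1 (such genes never enter
    APA testing).
    """
    if ns <= 0:
        raise ValueError("NS must be a positive integer")
    if ns == 1:
        return np.array([1.0])
    i = np.arange(1, ns + 1, dtype=float)
    return 1.0 - (i - 1.0) / (ns - 1.0)


def gene_length_score(cpm: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """score[sample] = sum_i W_i * cpm[i, sample]."""
    cpm = np.asarray(cpm, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if cpm.ndim == 1:
        cpm = cpm[:, None]
    if cpm.shape[0] != weights.shape[0]:
        raise ValueError("weights length must equal the number of sites")
    return weights @ cpm


def length_scores(
    cpm_table: pd.DataFrame,
    design: pd.DataFrame,
    proportion_based: bool = False,
) -> pd.DataFrame:
    """Per-gene length scores and the relative length change.

    ``proportion_based=True`` replaces CPM with within-gene usage fractions
    before weighting (scores then lie in [0, 1]); the default follows the
    printed definition, a weighted CPM sum, so expression changes leak into
    the score.
    """
    check_design(design)
    samples = design["sample"].tolist()
    ctrl = condition_samples(design, CONTROL)
    trt = condition_samples(design, TREATED)
    rows = []
    for gene, sub in cpm_table.groupby("gene_id", sort=True):
        sub = sub.sort_values("site_index")
        mat = sub[samples].to_numpy(dtype=float)
        if proportion_based:
            totals = mat.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                mat = np.where(totals > 0, mat / np.maximum(totals, 1e-300), 0.0)
        w = site_weights(mat.shape[0])
        scores = gene_length_score(mat, w)
        by_sample = dict(zip(samples, scores))
        mean_ctrl = float(np.mean([by_sample[s] for s in ctrl]))
        mean_trt = float(np.mean([by_sample[s] for s in trt]))
        rows.append(
            {
                "gene_id": gene,
                **{f"score_{s}": by_sample[s] for s in samples},
                "mean_control": mean_ctrl,
                "mean_treated": mean_trt,
                "length_change": mean_trt - mean_ctrl,
            }
        )
    return pd.DataFrame(rows)


def merge_apa_results(
    scores: pd.DataFrame, apa_results: pd.DataFrame
) -> pd.DataFrame:
    """Join length changes onto the DM test results (volcano-style table)."""
    return apa_results.merge(
        scores[["gene_id", "mean_control", "mean_treated", "length_change"]],
        on="gene_id",
        how="inner",
    )


@dataclass
class EnrichmentResult:
    chi2: float
    df: int
    pvalue: float
    n_short: int
    n_long: int
    n_zero: int


def shortening_chi2(n_short: int, n_long: int) -> tuple[float, int, float]:
    """Goodness-of-fit of (n_short, n_long) against an equal split."""
    chi2, df, p = gof_chi2([n_short, n_long])
    return chi2, df, p


def shortening_enrichment(
    results: pd.DataFrame, alpha: float = 0.05
) -> EnrichmentResult:
    """Two-tailed chi-square on shortened vs lengthened significant genes.

    Genes with ``adj_pvalue < alpha`` enter; zero-change genes are excluded
    and counted. Returns NaN statistics (with a warning) when no significant
    genes exist.
    """
    sig = results[results["adj_pvalue"] < alpha]
    n_zero = int((sig["length_change"] == 0).sum())
    n_short = int((sig["length_change"] < 0).sum())
    n_long = int((sig["length_change"] > 0).sum())
    if n_short + n_long == 0:
        warnings.warn("no significant genes with nonzero length change")
        return EnrichmentResult(np.nan, 1, np.nan, n_short, n_long, n_zero)
    chi2, df, p = shortening_chi2(n_short, n_long)
    return EnrichmentResult(chi2, df, p, n_short, n_long, n_zero)
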