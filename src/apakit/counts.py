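"""Three-stage count filtering and CPM normalisation.

All operations act on a long-format site table (one row per gene x site with
one integer column per sample) plus a sample->condition design, mirroring the
TSV interfaces. Filter order is fixed: low-support sites -> minor-usage
sites -> unexpressed genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from apakit._util import CONTROL, TREATED, check_design, condition_samples

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["gene_id", "site_index"]


def _counts(df: pd.DataFrame, samples: list[str]) -> np.ndarray:
    return df[samples].to_numpy(dtype=float)


def filter_low_support_sites(
    table: pd.DataFrame,
    design: pd.DataFrame,
    min_major: int = 5,
    min_minor: int = 1,
) -> pd.DataFrame:
    """Keep sites with >= ``min_major`` reads in all-but-one sample and
    >= ``min_minor`` in the remaining sample, in at least one condition.

    For the 3-vs-3 design this is exactly "five reads in two samples and one
    read in the remaining sample in either of the conditions"; for other n it
    generalises to (n-1 samples >= major, last sample >= minor).
    """
    check_design(design)
    keep = np.zeros(len(table), dtype=bool)
    for cond in (CONTROL, TREATED):
        cols = condition_samples(design, cond)
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 samples")
        x = np.sort(_counts(table, cols), axis=1)  # ascending
        ok = (x[:, 0] >= min_minor) & (x[:, 1:] >= min_major).all(axis=1)
        keep |= ok
    return table[keep].reset_index(drop=True)


def filter_minor_usage_sites(
    table: pd.DataFrame, design: pd.DataFrame, min_fraction: float = 0.10
) -> pd.DataFrame:
    """Drop sites below ``min_fraction`` of their gene's condition-summed
    reads in BOTH conditions (zero gene totals count as fraction 0)."""
    check_design(design)
    remove = np.zeros(len(table), dtype=bool)
    below = np.ones(len(table), dtype=bool)
    for cond in (CONTROL, TREATED):
        cols = condition_samples(design, cond)
        site_sum = _counts(table, cols).sum(axis=1)
        gene_sum = table.groupby("gene_id")[cols].transform("sum").sum(axis=1).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(gene_sum > 0, site_sum / np.maximum(gene_sum, 1), 0.0)
        below &= frac < min_fraction
    remove = below
    return table[~remove].reset_index(drop=True)


def filter_unexpressed_genes(
    table: pd.DataFrame,
    design: pd.DataFrame,
    min_mean: float = 5.0,
    drop_single_site: bool = True,
) -> pd.DataFrame:
    """Keep genes whose mean total count is >= ``min_mean`` in BOTH
    conditions; genes reduced to one site are excluded from APA testing
    (logged) when ``drop_single_site`` is set."""
    check_design(design)
    keep_genes = []
    single_site = []
    for gene, sub in table.groupby("gene_id", sort=False):
        expressed = True
        for cond in (CONTROL, TREATED):
            cols = condition_samples(design, cond)
            totals = sub[cols].sum(axis=0).to_numpy(dtype=float)
            if totals.mean() < min_mean:
                expressed = False
                break
        if not expressed:
            continue
        if drop_single_site and len(sub) < 2:
            single_site.append(gene)
            continue
        keep_genes.append(gene)
    if single_site:
        logger.info(
            "%d expressed genes reduced to a single site; excluded from APA "
            "testing: %s",
            len(single_site),
            ",".join(map(str, single_site[:10])),
        )
    return table[table["gene_id"].isin(keep_genes)].reset_index(drop=True)


def apply_filters(
    table: pd.DataFrame,
    design: pd.DataFrame,
    min_major: int = 5,
    min_minor: int = 1,
    min_fraction: float = 0.10,
    min_mean: float = 5.0,
) -> pd.DataFrame:
    """Fixed-order composition of the three filters."""
    out = filter_low_support_sites(table, design, min_major, min_minor)
    out = filter_minor_usage_sites(out, design, min_fraction)
    return filter_unexpressed_genes(out, design, min_mean)


def cpm_normalize(table: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Counts per million over each sample's total retained poly(A)-site
    reads (across all genes)."""
    check_design(design)
    out = table.copy()
    for sample in design["sample"]:
        total = float(table[sample].sum())
        if total == 0:
            raise ValueError(f"sample {sample!r} has zero retained reads")
        out[sample] = table[sample].astype(float) * 1e6 / total
    return out
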