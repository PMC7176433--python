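"""Proteomics arm: normalisation, consistency filter, downshifted-Gaussian
imputation, empirical-Bayes moderated t-test, and the conditional chi-square
battery joining protein change to mRNA length change.

Intensity tables are proteins x samples on the linear scale with NaN for
missing; tests operate on log2 values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma

from apakit._util import (
    CONTROL,
    TREATED,
    bh_adjust,
    check_design,
    condition_samples,
    gof_chi2,
)


def median_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its median quantified intensity equals the grand
    median of the pre-scaling per-sample medians. Missing values untouched."""
    medians = table.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = medians.index[medians.isna()].tolist()
        raise ValueError(f"samples with no quantified values: {bad}")
    grand = float(np.median(medians.to_numpy()))
    return table * (grand / medians)


def filter_consistent(table: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Keep proteins quantified in every sample of at least one condition."""
    check_design(design)
    keep = np.zeros(len(table), dtype=bool)
    for cond in (CONTROL, TREATED):
        cols = condition_samples(design, cond)
        keep |= table[cols].notna().all(axis=1).to_numpy()
    return table[keep]


def impute_missing(
    log2_matrix: pd.DataFrame,
    downshift: float = 2.0,
    width: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing log2 values with draws from Normal(mean - downshift*SD,
    (width*SD)^2), both moments taken over ALL measured values.

    Returns (complete matrix, boolean imputed-mask). Measured entries are
    bit-identical to the input.
    """
    values = log2_matrix.to_numpy(dtype=float)
    measured = np.isfinite(values)
    obs = values[measured]
    if obs.size < 2:
        raise ValueError("need >= 2 measured values to impute")
    sd = float(obs.std(ddof=1))
    if sd == 0:
        raise ValueError("measured values have zero standard deviation")
    mu = float(obs.mean()) - downshift * sd
    rng = np.random.default_rng(seed)
    out = values.copy()
    n_missing = int((~measured).sum())
    out[~measured] = rng.normal(mu, width * sd, size=n_missing)
    complete = pd.DataFrame(out, index=log2_matrix.index, columns=log2_matrix.columns)
    mask = pd.DataFrame(
        ~measured, index=log2_matrix.index, columns=log2_matrix.columns
    )
    return complete, mask


@dataclass
class EbPrior:
    """Empirical-Bayes variance prior: d0 degrees of freedom (np.inf allowed)
    and prior variance s0_sq."""

    d0: float
    s0_sq: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: int) -> EbPrior:
    """Moment estimation of (d0, s0_sq) on log s^2 (Smyth-style)."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive residual variances")
    z = np.log(s2[ok])
    e = z - polygamma(0, df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - polygamma(1, df / 2.0)
    if excess <= 0:
        return EbPrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    x = _trigamma_inverse(float(excess))
    d0 = 2.0 * x
    s0_sq = float(np.exp(e_mean + polygamma(0, x) - np.log(x)))
    return EbPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    log2_matrix: pd.DataFrame,
    design: pd.DataFrame,
    prior: EbPrior | None = None,
) -> tuple[pd.DataFrame, EbPrior]:
    """Per-protein moderated t-test of treated vs control.

    Residual variances are shrunk toward an empirically estimated prior:
    s_tilde^2 = (d0*s0^2 + d*s^2)/(d0 + d), with the t reference on d0 + d
    degrees of freedom. ``prior`` pins (d0, s0_sq) instead of estimating
    (d0 = 0 reduces to the ordinary t-test, d0 = inf to a pooled-variance
    z-like statistic). BH adjustment across proteins.
    """
    check_design(design)
    ctrl = condition_samples(design, CONTROL)
    trt = condition_samples(design, TREATED)
    n1, n2 = len(ctrl), len(trt)
    d = n1 + n2 - 2
    if d <= 0:
        raise ValueError("zero residual degrees of freedom")
    xc = log2_matrix[ctrl].to_numpy(dtype=float)
    xt = log2_matrix[trt].to_numpy(dtype=float)
    if not (np.isfinite(xc).all() and np.isfinite(xt).all()):
        raise ValueError("matrix contains missing values; impute first")
    fc = xt.mean(axis=1) - xc.mean(axis=1)
    ss = xc.var(axis=1, ddof=1) * (n1 - 1) + xt.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d
    if prior is None:
        prior = estimate_prior(s2, d)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    elif prior.d0 == 0:
        s2_post = s2
        df_total = float(d)
    else:
        s2_post = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = pd.DataFrame(
        {
            "gene_id": log2_matrix.index,
            "log2fc": fc,
            "t_mod": t_mod,
            "pvalue": p,
            "adj_pvalue": bh_adjust(p),
            "s2": s2,
            "s2_post": s2_post,
        }
    ).reset_index(drop=True)
    return out, prior


@dataclass
class ChiSquareStep:
    name: str
    chi2: float
    df: int
    pvalue: float
    counts: dict[str, int]
    n_excluded: int


def quadrant_tests(
    merged: pd.DataFrame, alpha: float = 0.05
) -> list[ChiSquareStep]:
    """Three-step conditional chi-square battery.

    ``merged`` joins per gene: length_change, adj_pvalue (APA test) and
    protein_log2fc. Step 1: shortened vs lengthened among APA-significant
    genes. Step 2: the four (length sign x protein sign) quadrants against
    uniform. Step 3: protein up vs down among shortened genes only. Zero
    cells in a required margin yield NaN with a warning, not an exception.
    """
    sig = merged[merged["adj_pvalue"] < alpha]
    steps: list[ChiSquareStep] = []

    n_zero_len = int((sig["length_change"] == 0).sum())
    n_short = int((sig["length_change"] < 0).sum())
    n_long = int((sig["length_change"] > 0).sum())
    if n_short + n_long == 0:
        warnings.warn("step 1: no significant genes")
        steps.append(
            ChiSquareStep("shortening", np.nan, 1, np.nan, {}, n_zero_len)
        )
    else:
        chi2, df, p = gof_chi2([n_short, n_long])
        steps.append(
            ChiSquareStep(
                "shortening",
                chi2,
                df,
                p,
                {"short": n_short, "long": n_long},
                n_zero_len,
            )
        )

    quant = sig[sig["protein_log2fc"].notna()]
    nonzero = quant[
        (quant["length_change"] != 0) & (quant["protein_log2fc"] != 0)
    ]
    n_excl = len(quant) - len(nonzero)
    short = nonzero["length_change"] < 0
    up = nonzero["protein_log2fc"] > 0
    quadrants = {
        "long_up": int((~short & up).sum()),
        "short_up": int((short & up).sum()),
        "short_down": int((short & ~up).sum()),
        "long_down": int((~short & ~up).sum()),
    }
    if len(nonzero) == 0:
        warnings.warn("step 2: no quantified significant genes")
        steps.append(ChiSquareStep("quadrants", np.nan, 3, np.nan, quadrants, n_excl))
    else:
        chi2, df, p = gof_chi2(list(quadrants.values()))
        steps.append(ChiSquareStep("quadrants", chi2, df, p, quadrants, n_excl))

    n_su, n_sd = quadrants["short_up"], quadrants["short_down"]
    if n_su + n_sd == 0:
        warnings.warn("step 3: no shortened genes with protein change")
        steps.append(ChiSquareStep("conditional_protein", np.nan, 1, np.nan, {}, 0))
    else:
        chi2, df, p = gof_chi2([n_su, n_sd])
        steps.append(
            ChiSquareStep(
                "conditional_protein",
                chi2,
                df,
                p,
                {"short_up": n_su, "short_down": n_sd},
                0,
            )
        )
    return steps
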