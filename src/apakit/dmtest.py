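"""Per-gene Dirichlet-multinomial likelihood-ratio test of site usage.

The model for one gene: each sample's site counts are Dirichlet-multinomial
with proportion vector pi (shared within a condition) and a single precision
(concentration) phi shared across conditions. The LRT compares a pooled fit
(one pi) against per-condition proportions; the statistic is referred to a
chi-square with (C - 1)(NS - 1) degrees of freedom, BH-adjusted across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma, gammaln, polygamma

from apakit._util import CONTROL, TREATED, bh_adjust, check_design, condition_samples

PROP_FLOOR = 1e-12
_LOG_PHI_BOUNDS = (np.log(1e-2), np.log(1e6))


def dm_loglik(counts: np.ndarray, proportions: np.ndarray, precision: float) -> float:
    """Dirichlet-multinomial log-likelihood (ordered-sequence form, without
    the multinomial coefficient) summed over sample columns.

    ``counts`` is sites x samples; ``proportions`` is either one vector of
    length NS or a sites x samples matrix giving each column its own vector.
    All-zero columns contribute exactly 0.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    pi = np.asarray(proportions, dtype=float)
    if pi.ndim == 1:
        pi = np.broadcast_to(pi[:, None], x.shape)
    if not (np.isfinite(x).all() and np.isfinite(pi).all() and np.isfinite(precision)):
        raise ValueError("non-finite inputs to dm_loglik")
    if precision <= 0:
        raise ValueError("precision must be positive")
    pi = np.maximum(pi, PROP_FLOOR)
    a = precision * pi
    n = x.sum(axis=0)
    ll = np.sum(gammaln(precision) - gammaln(n + precision))
    ll += np.sum(gammaln(x + a) - gammaln(a))
    return float(ll)


@dataclass
class DmFit:
    """Fitted proportions (per condition, or a single 'pooled' entry), the
    shared precision, and optimiser diagnostics."""

    proportions: dict[str, np.ndarray]
    precision: float
    loglik: float
    converged: bool
    n_iter: int


def _cr_logdet(x: np.ndarray, pi: np.ndarray, phi: float) -> float:
    """Log-determinant of the observed information for the NS-1 free
    proportions of one group (Cox-Reid adjustment term).

    The information matrix has the form phi^2 * (diag(a) + b 11'), so the
    determinant follows from the matrix determinant lemma.
    """
    a_full = phi * np.maximum(pi, PROP_FLOOR)
    tri = polygamma(1, x + a_full[:, None]) - polygamma(1, a_full[:, None])
    col = -tri.sum(axis=1)  # positive
    a, b = np.maximum(col[:-1], 1e-300), col[-1]
    return float(
        np.sum(np.log(a))
        + np.log1p(b * np.sum(1.0 / a))
        + 2 * (len(pi) - 1) * np.log(phi)
    )


def _update_proportions(
    x: np.ndarray, pi: np.ndarray, phi: float
) -> np.ndarray:
    """One fixed-point (expectation-style) update of pi at fixed phi."""
    a = np.maximum(phi * pi, PROP_FLOOR)
    num = np.sum(digamma(x + a[:, None]) - digamma(a[:, None]), axis=1)
    new = a * num
    total = new.sum()
    if total <= 0:
        return pi
    new = np.maximum(new / total, PROP_FLOOR)
    return new / new.sum()


def fit_dm(
    counts: np.ndarray,
    design: pd.DataFrame | None = None,
    samples: list[str] | None = None,
    pooled: bool = True,
    precision: float | None = None,
    cr_adjust: bool = False,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> DmFit:
    """Maximise the DM likelihood over proportions and a shared precision.

    Pooled fits estimate one proportion vector for all columns; unpooled fits
    one per condition (requires ``design`` and the column sample order).
    Proportions are updated by fixed-point iteration; the precision by a
    bounded 1-D search on log phi in [log 1e-2, log 1e6], unless pinned via
    ``precision``. With ``cr_adjust`` the precision search maximises the
    Cox-Reid adjusted profile likelihood, which counteracts the upward
    small-sample bias of the precision MLE.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("untestable gene: need >= 2 sites")
    if not (x.sum(axis=0) > 0).any():
        raise ValueError("need at least one nonzero sample column")

    if pooled:
        groups = {"pooled": np.arange(x.shape[1])}
    else:
        if design is None or samples is None:
            raise ValueError("unpooled fit needs design and sample order")
        check_design(design)
        cond_of = dict(zip(design["sample"], design["condition"]))
        groups = {}
        for cond in (CONTROL, TREATED):
            idx = [j for j, s in enumerate(samples) if cond_of[s] == cond]
            if idx:
                groups[cond] = np.array(idx)

    pis = {}
    for name, idx in groups.items():
        tot = x[:, idx].sum(axis=1) + 0.5
        pis[name] = tot / tot.sum()
    phi = precision if precision is not None else 10.0
    if phi <= 0:
        raise ValueError("precision must be positive")

    def total_ll(phi_val: float, props: dict[str, np.ndarray]) -> float:
        return sum(
            dm_loglik(x[:, idx], props[name], phi_val) for name, idx in groups.items()
        )

    def objective(phi_val: float, props: dict[str, np.ndarray]) -> float:
        val = total_ll(phi_val, props)
        if cr_adjust:
            val -= sum(
                0.5 * _cr_logdet(x[:, idx], props[name], phi_val)
                for name, idx in groups.items()
            )
        return val

    obj = objective(phi, pis)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for name, idx in groups.items():
            pis[name] = _update_proportions(x[:, idx], pis[name], phi)
        if precision is None:
            res = optimize.minimize_scalar(
                lambda lp: -objective(np.exp(lp), pis),
                bounds=_LOG_PHI_BOUNDS,
                method="bounded",
                options={"xatol": 1e-6},
            )
            phi = float(np.exp(res.x))
        new_obj = objective(phi, pis)
        if abs(new_obj - obj) < tol:
            converged = True
            break
        obj = new_obj
    ll = total_ll(phi, pis)
    return DmFit(
        proportions=pis, precision=phi, loglik=ll, converged=converged, n_iter=it
    )


def _common_precision(
    matrices: dict[str, np.ndarray], group_idx: list[np.ndarray]
) -> float:
    """Study-wide precision maximising the summed Cox-Reid adjusted profile
    likelihood of the full (per-condition proportions) model over genes."""
    pis: dict[str, list[np.ndarray]] = {}
    for g, x in matrices.items():
        starts = []
        for idx in group_idx:
            tot = x[:, idx].sum(axis=1) + 0.5
            starts.append(tot / tot.sum())
        pis[g] = starts

    def apl(phi: float) -> float:
        total = 0.0
        for g, x in matrices.items():
            for k, idx in enumerate(group_idx):
                pi = pis[g][k]
                for _ in range(3):  # warm-started profile step
                    pi = _update_proportions(x[:, idx], pi, phi)
                pis[g][k] = pi
                total += dm_loglik(x[:, idx], pi, phi)
                total -= 0.5 * _cr_logdet(x[:, idx], pi, phi)
        return total

    res = optimize.minimize_scalar(
        lambda lp: -apl(np.exp(lp)),
        bounds=_LOG_PHI_BOUNDS,
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(np.exp(res.x))


def lrt_apa(
    table: pd.DataFrame,
    design: pd.DataFrame,
    precision: str | float = "common",
    max_iter: int = 200,
) -> pd.DataFrame:
    """Likelihood-ratio test per gene on a filtered long-format site table.

    Precision handling (shared between the null and alternative fits of each
    gene so dispersion misestimation cancels out of the statistic):

    - ``"common"`` (default): one study-wide precision maximising the summed
      Cox-Reid adjusted profile likelihood of the full model over all genes;
      every gene is tested at that precision. With 3-vs-3 designs a per-gene
      estimate is too noisy to give both nominal type-I error and power.
    - ``"genewise"``: each gene keeps its own Cox-Reid adjusted estimate
      (anti-conservative in small designs; provided for sensitivity checks).
    - a float pins the precision directly.

    Returns a frame with columns gene_id, ns, lr, df, pvalue, adj_pvalue,
    precision and converged, sorted by p-value. Sites with zero counts in
    every sample are dropped before testing so they cannot affect any
    statistic; genes left with < 2 sites are skipped.
    """
    check_design(design)
    samples = design["sample"].tolist()

    matrices: dict[str, np.ndarray] = {}
    for gene, sub in table.groupby("gene_id", sort=True):
        x = sub.sort_values("site_index")[samples].to_numpy(dtype=float)
        x = x[x.sum(axis=1) > 0]
        if x.shape[0] >= 2:
            matrices[gene] = x

    cond_of = dict(zip(design["sample"], design["condition"]))
    group_idx = [
        np.array([j for j, s in enumerate(samples) if cond_of[s] == cond])
        for cond in (CONTROL, TREATED)
    ]

    phi_of: dict[str, float] = {}
    if isinstance(precision, (int, float)):
        phi_of = {g: float(precision) for g in matrices}
    elif precision == "common":
        if matrices:
            common = _common_precision(matrices, group_idx)
            phi_of = {g: common for g in matrices}
    elif precision == "genewise":
        phi_of = {
            g: fit_dm(
                x,
                design=design,
                samples=samples,
                pooled=False,
                cr_adjust=True,
                max_iter=max_iter,
            ).precision
            for g, x in matrices.items()
        }
    else:
        raise ValueError("precision must be 'common', 'genewise' or a number")

    rows = []
    for gene, x in matrices.items():
        phi = phi_of[gene]
        fit0 = fit_dm(x, pooled=True, precision=phi, max_iter=max_iter)
        fit1 = fit_dm(
            x,
            design=design,
            samples=samples,
            pooled=False,
            precision=phi,
            max_iter=max_iter,
        )
        lr = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
        df = (len(fit1.proportions) - 1) * (x.shape[0] - 1)
        rows.append(
            {
                "gene_id": gene,
                "ns": x.shape[0],
                "lr": lr,
                "df": df,
                "pvalue": float(stats.chi2.sf(lr, df)),
                "precision": phi,
                "converged": bool(fit0.converged and fit1.converged),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "ns", "lr", "df", "pvalue", "precision", "converged"],
    )
    if len(out):
        out["adj_pvalue"] = bh_adjust(out["pvalue"].to_numpy())
        out = out.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
    else:
        out["adj_pvalue"] = pd.Series(dtype=float)
    return out
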