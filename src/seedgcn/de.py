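"""Differential expression by empirical-Bayes moderated t.

Per gene, a two-group comparison on the log2 scale: logFC is the case-mean
minus control-mean, the residual variance s_g^2 has d_g = n - 2 degrees of
freedom, and an inverse-chi-square prior (d0, s0^2) estimated from the
ensemble of genes by moments matching on log s_g^2 shrinks each gene's
variance toward the common value:

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_mod  = logFC / (s~_g * sqrt(1/n1 + 1/n2)),   df = d0 + d_g

Multiplicity is controlled with Benjamini-Hochberg, and genes are called
differentially expressed when the adjusted p falls below ``alpha`` and the
linear-scale fold change exceeds ``fc_min`` (i.e. |logFC| > log2(fc_min)).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .expression import CASE, CONTROL, ExpressionMatrix

logger = logging.getLogger(__name__)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Monotone decreasing target; the Newton update is performed on 1/y using
    the asymptotic behaviour trigamma(y) ~ 1/y for large y, which converges
    from any positive start.
    """
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df_residual: float) -> tuple[float, float]:
    """Moments-matching estimate of the variance prior (d0, s0^2).

    Fits a scaled F distribution to the positive residual variances via the
    moments of log s_g^2: the excess spread of z = log s^2 beyond the
    chi-square sampling noise trigamma(d_g/2) identifies trigamma(d0/2). A
    non-positive excess yields d0 = +inf (all variances shrink fully to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 genes with positive residual variance")
    z = np.log(s2[ok])
    dg = df_residual
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1)
    excess = evar - special.polygamma(1, dg / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    else:
        d0 = 2.0 * _trigamma_inverse(float(excess))
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_2


def moderated_t(matrix: ExpressionMatrix, prior_df: float | None = None) -> pd.DataFrame:
    """Per-gene moderated t comparison of case vs control samples.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Every sample must carry a case/control label; each group needs >= 2
        samples and the matrix >= 10 genes (the prior is estimated from the
        gene ensemble).
    prior_df : float, optional
        Override the estimated prior degrees of freedom d0 (0 recovers the
        ordinary pooled two-sample t; +inf fixes every posterior variance at
        s0^2). s0^2 is always estimated from the data.

    Returns
    -------
    pandas.DataFrame indexed by gene with columns logFC, t_mod, df_total,
    p_raw (no multiplicity adjustment; see :func:`bh_adjust`).
    """
    cases = matrix.samples_in_group(CASE)
    controls = matrix.samples_in_group(CONTROL)
    unlabeled = [s for s in matrix.sample_ids if s not in cases and s not in controls]
    if unlabeled:
        raise ValueError(f"samples without group label: {unlabeled}")
    n1, n0 = len(cases), len(controls)
    if n1 < 2 or n0 < 2:
        raise ValueError(f"each group needs >= 2 samples (got {n1} case, {n0} control)")
    if matrix.n_genes < 10:
        raise ValueError("prior estimation needs >= 10 genes")

    x1 = matrix.values[cases].to_numpy(dtype=float)
    x0 = matrix.values[controls].to_numpy(dtype=float)
    m1 = x1.mean(axis=1)
    m0 = x0.mean(axis=1)
    logfc = m1 - m0
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x0 - m0[:, None]) ** 2).sum(axis=1)
    dg = n1 + n0 - 2
    s2 = ss / dg

    d0, s0_2 = estimate_prior(s2, dg)
    if prior_df is not None:
        d0 = float(prior_df)
    logger.info("variance prior: d0=%.4g, s0^2=%.4g", d0, s0_2)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.full_like(s2, np.inf)
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = np.full_like(s2, float(dg))
    else:
        s2_post = (d0 * s0_2 + dg * s2) / (d0 + dg)
        df_total = np.full_like(s2, d0 + dg)

    se_factor = np.sqrt(1.0 / n1 + 1.0 / n0)
    t = np.zeros_like(logfc)
    p = np.ones_like(logfc)
    zero_var = s2_post <= 0
    # zero posterior variance only arises with d0=0 and a flat gene; fall
    # back to the prior-only variance so the gene is not silently dropped
    if np.any(zero_var):
        nz = zero_var & (logfc != 0)
        if np.any(nz) and s0_2 > 0:
            t[nz] = logfc[nz] / (np.sqrt(s0_2) * se_factor)
            p[nz] = 2.0 * stats.t.sf(np.abs(t[nz]), df=max(d0, 1.0) if np.isfinite(d0) and d0 > 0 else dg)
    ok = ~zero_var
    t[ok] = logfc[ok] / (np.sqrt(s2_post[ok]) * se_factor)
    finite_df = np.where(np.isfinite(df_total[ok]), df_total[ok], 1e12)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=finite_df)

    out = pd.DataFrame(
        {"logFC": logfc, "t_mod": t, "df_total": df_total, "p_raw": p},
        index=matrix.values.index.copy(),
    )
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(table: pd.DataFrame, alpha: float = 0.05, fc_min: float = 1.5) -> pd.DataFrame:
    """Flag DEGs: adjusted p < alpha and |logFC| > log2(fc_min).

    Adds columns p_adj (if absent), is_deg and direction (up/down by the sign
    of logFC).
    """
    out = table.copy()
    if "p_adj" not in out.columns:
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    lfc_min = np.log2(fc_min)
    out["is_deg"] = (out["p_adj"] < alpha) & (out["logFC"].abs() > lfc_min)
    out["direction"] = np.where(out["logFC"] >= 0, "up", "down")
    n_up = int((out["is_deg"] & (out["direction"] == "up")).sum())
    n_down = int((out["is_deg"] & (out["direction"] == "down")).sum())
    logger.info("DEGs: %d up, %d down (alpha=%g, fc_min=%g)", n_up, n_down, alpha, fc_min)
    return out
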