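"""Seed-correlation screening of DEGs within the case cohort.

DEGs whose expression correlates with the seed gene across case samples
(two-sided Pearson p below ``alpha``) are flagged as seed-associated ("AA")
genes and split into positively and negatively correlated subsets; network
construction downstream uses only the positive subset.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


def _check_vector(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.ptp(v) == 0:
        raise ValueError(f"vector {name!r} has zero variance")
    return v


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value.

    p comes from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df; |r| = 1 gives p = 0.
    """
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length n >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on mid-ranks), two-sided p."""
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length n >= 3")
    rs, p = stats.spearmanr(x, y)
    return float(rs), float(p)


def correlate_with_seed(matrix: ExpressionMatrix, seed: str, genes=None) -> pd.DataFrame:
    """Pearson r and p of every gene against the seed, vectorised.

    Returns a DataFrame (r, p_raw) indexed by gene, excluding the seed itself.
    Genes with zero variance get r = 0, p = 1 (they cannot show association).
    """
    if seed not in matrix.values.index:
        raise KeyError(f"seed gene {seed!r} not in matrix")
    if genes is None:
        genes = [g for g in matrix.gene_ids if g != seed]
    else:
        genes = [g for g in genes if g != seed]
        missing = [g for g in genes if g not in matrix.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
    s = matrix.gene(seed)
    n = s.size
    if n < 3:
        raise ValueError("need >= 3 samples for correlation")
    if np.ptp(s) == 0:
        raise ValueError(f"seed gene {seed!r} has zero variance")
    x = matrix.values.loc[genes].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (sc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc @ sc / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(denom > 0, p, 1.0)
    return pd.DataFrame({"r": r, "p_raw": p}, index=pd.Index(genes, name="gene_id"))


def screen_aa_genes(
    matrix: ExpressionMatrix,
    seed: str,
    degs: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Screen DEGs for association with the seed over case samples.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Restricted to (or restrictable to) case samples; the screen always
        runs on the case cohort only.
    seed : str
        Seed gene id; must be a DEG present in the matrix.
    degs : pandas.DataFrame
        Output of :func:`seedgcn.de.select_degs` with an ``is_deg`` column.
    alpha : float
        Significance cut on the correlation p (raw by default; BH-adjusted
        with ``use_adjusted=True``).

    Returns
    -------
    DataFrame indexed by gene with r, p_raw, p_adj, sign (positive/negative)
    and is_aa; the seed itself is excluded.
    """
    cases = matrix.cases_only() if matrix.sample_groups else matrix
    if seed not in cases.values.index:
        raise KeyError(f"seed gene {seed!r} not in matrix")
    if seed not in degs.index or not bool(degs.loc[seed, "is_deg"]):
        raise ValueError(f"seed gene {seed!r} is not a DEG")
    deg_genes = [g for g in degs.index[degs["is_deg"]] if g != seed and g in cases.values.index]
    if not deg_genes:
        raise ValueError("no DEGs to screen against the seed")
    tab = correlate_with_seed(cases, seed, deg_genes)
    tab["p_adj"] = bh_adjust(tab["p_raw"].to_numpy())
    tab["sign"] = np.where(tab["r"] > 0, "positive", "negative")
    pcol = "p_adj" if use_adjusted else "p_raw"
    tab["is_aa"] = tab[pcol] < alpha
    n_pos = int((tab["is_aa"] & (tab["sign"] == "positive")).sum())
    n_neg = int((tab["is_aa"] & (tab["sign"] == "negative")).sum())
    logger.info("AA genes: %d positive, %d negative (alpha=%g on %s)", n_pos, n_neg, alpha, pcol)
    return tab


def positive_aa_genes(table: pd.DataFrame) -> list[str]:
    """The positively seed-correlated AA genes, the GCN candidate set."""
    return list(table.index[table["is_aa"] & (table["sign"] == "positive")])
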