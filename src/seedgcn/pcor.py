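"""First-order partial correlation for confounder adjustment.

Reassesses the seed-gene associations while removing the linear effect of a
single conditioning gene (e.g. a glycolysis rate-limiting enzyme):

    r_p = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) * (1 - r_yz^2))

with a two-sided p from t = r_p * sqrt(n-3) / sqrt(1 - r_p^2) on n-3 df.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .association import pearson
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


def partial_corr(x, y, z) -> tuple[float, float]:
    """Partial correlation of x and y given z, with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if not (y.size == n == z.size) or n < 4:
        raise ValueError("vectors must have equal length n >= 4")
    r_xy, _ = pearson(x, y)
    r_xz, _ = pearson(x, z)
    r_yz, _ = pearson(y, z)
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("conditioning variable is collinear with x or y")
    r_p = (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz ** 2) * (1.0 - r_yz ** 2))
    r_p = float(np.clip(r_p, -1.0, 1.0))
    if abs(r_p) >= 1.0:
        return r_p, 0.0
    t = r_p * np.sqrt((n - 3) / (1.0 - r_p ** 2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 3))
    return r_p, p


def reassess_hubs(
    matrix: ExpressionMatrix,
    seed: str,
    genes,
    confounders,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Seed-gene partial correlations, one conditioning gene at a time.

    For every (gene, confounder) pair: r_p and its p, plus the marginal
    Pearson r/p for reference and a ``significant`` flag (p < alpha on the
    partial p). Rows sorted by confounder then r_p descending.
    """
    genes = [g for g in genes if g != seed]
    if not genes:
        raise ValueError("no genes to reassess")
    for g in [seed, *confounders]:
        if g not in matrix.values.index:
            raise KeyError(f"gene {g!r} not in matrix")
    x = matrix.gene(seed)
    rows = []
    for conf in confounders:
        z = matrix.gene(conf)
        if np.ptp(z) == 0:
            raise ValueError(f"confounder {conf!r} has zero variance")
        for g in genes:
            if g == conf:
                continue
            y = matrix.gene(g)
            r, p_marg = pearson(x, y)
            r_p, p = partial_corr(x, y, z)
            rows.append({
                "gene_id": g, "confounder": conf, "r": r, "p_marginal": p_marg,
                "r_p": r_p, "p": p, "significant": p < alpha,
            })
    out = pd.DataFrame(rows).sort_values(["confounder", "r_p"],
                                         ascending=[True, False]).reset_index(drop=True)
    n_lost = int((~out["significant"]).sum())
    logger.info("partial correlation: %d of %d gene-confounder pairs lose significance",
                n_lost, len(out))
    return out
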