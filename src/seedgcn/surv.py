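"""Kaplan-Meier survival analysis of marker-defined patient groups.

Median dichotomization of marker expression (high = strictly above the
median), product-limit survival estimation with Greenwood variance, two-group
log-rank tests, a combined high/high marker group, and fixed-horizon
comparison of overall-survival rates by a normal Z-test

    z = (S_A(h) - S_B(h)) / sqrt(V_A(h) + V_B(h))

with the Greenwood variances at the horizon h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit estimate over the distinct event (death) times.

    Arrays are aligned: at ``times[i]`` there were ``at_risk[i]`` patients at
    risk (censoring ties at an event time count as at risk), ``deaths[i]``
    deaths, survival ``s[i]`` just after the time, and Greenwood variance
    ``var[i]``. Before the first event S = 1, V = 0.
    """

    times: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    s: np.ndarray
    var: np.ndarray
    max_followup: float


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimator with Greenwood variance.

    S(t) = prod_{t_i <= t} (1 - d_i/n_i);
    V(t) = S(t)^2 * sum_{t_i <= t} d_i / (n_i * (n_i - d_i)).
    When the last patient at risk dies (n_i = d_i) S drops to 0 and the
    variance is reported as 0 from that time on.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty cohort")
    if time.size != event.size:
        raise ValueError("time and event must align")
    if not np.all(np.isfinite(time)) or np.any(time < 0):
        raise ValueError("times must be finite and non-negative")
    if not np.all(np.isin(event, (0, 1))):
        raise ValueError("event indicator must be 0/1")

    ev_times = np.unique(time[event == 1])
    s_vals, var_vals, n_vals, d_vals = [], [], [], []
    s = 1.0
    gsum = 0.0
    for t in ev_times:
        n_i = int(np.sum(time >= t))
        d_i = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            gsum += d_i / (n_i * (n_i - d_i))
            v = s * s * gsum
        else:
            v = 0.0  # S hit zero; Greenwood sum is undefined past this point
        n_vals.append(n_i)
        d_vals.append(d_i)
        s_vals.append(s)
        var_vals.append(v)
    return KMCurve(
        times=ev_times,
        at_risk=np.asarray(n_vals, dtype=int),
        deaths=np.asarray(d_vals, dtype=int),
        s=np.asarray(s_vals, dtype=float),
        var=np.asarray(var_vals, dtype=float),
        max_followup=float(time.max()),
    )


def survival_at(curve: KMCurve, t: float) -> tuple[float, float]:
    """(S(t), Greenwood V(t)) of the step function at time t."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0, 0.0
    return float(curve.s[idx]), float(curve.var[idx])


def dichotomize_by_median(values, sample_ids=None) -> pd.Series:
    """Split marker values at the median: strictly above -> "high", else "low"."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 patients to dichotomize")
    if np.ptp(v) == 0:
        raise ValueError("all marker values identical: degenerate median split")
    med = float(np.median(v))
    labels = np.where(v > med, "high", "low")
    idx = pd.Index(sample_ids, name="sample_id") if sample_ids is not None else None
    out = pd.Series(labels, index=idx)
    logger.info("median split at %.4g: %d high, %d low", med,
                int((labels == "high").sum()), int((labels == "low").sum()))
    return out


def combined_group(high_seed: pd.Series, high_partner: pd.Series) -> pd.Series:
    """"HH" for patients high on both markers, "others" for the rest."""
    if not high_seed.index.equals(high_partner.index):
        raise ValueError("marker splits must cover the same patients")
    hh = (high_seed == "high") & (high_partner == "high")
    return pd.Series(np.where(hh, "HH", "others"), index=high_seed.index)


def logrank(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p)."""
    ea = np.asarray(event_a, dtype=int)
    eb = np.asarray(event_b, dtype=int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank undefined: no events in either group")
    res = logrank_test(np.asarray(time_a, dtype=float), np.asarray(time_b, dtype=float),
                       event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def os_rate_ztest(time_a, event_a, time_b, event_b, horizon: float) -> dict:
    """Compare overall-survival rates at a fixed horizon by Z-test.

    Rates are the Kaplan-Meier estimates at the horizon; the variance of the
    difference is the sum of the two Greenwood variances there. Requires the
    horizon to lie within both groups' observed follow-up, and at least one
    event before the horizon somewhere (otherwise the variance is zero).
    """
    curve_a = km_estimate(time_a, event_a)
    curve_b = km_estimate(time_b, event_b)
    for name, c in (("A", curve_a), ("B", curve_b)):
        if horizon > c.max_followup:
            raise ValueError(
                f"horizon {horizon} exceeds group {name} follow-up ({c.max_followup:g})")
    sa, va = survival_at(curve_a, horizon)
    sb, vb = survival_at(curve_b, horizon)
    if va + vb == 0:
        raise ValueError("zero variance at the horizon: no informative events")
    z = (sa - sb) / np.sqrt(va + vb)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return {"rate_a": sa, "rate_b": sb, "var_a": va, "var_b": vb,
            "z": float(z), "p": p, "horizon": float(horizon)}


def marker_survival_table(
    survival: pd.DataFrame,
    expression: pd.DataFrame,
    seed: str,
    partners,
    horizons=(3.0, 5.0),
) -> pd.DataFrame:
    """Per-partner survival comparisons mirroring a marker-combination table.

    For each partner gene: the high-vs-low split on the partner alone and the
    combined HH-vs-others grouping (high on both partner and seed), each with
    the log-rank test and the fixed-horizon Z-tests.
    """
    patients = survival.index
    rows = []
    seed_split = dichotomize_by_median(expression.loc[seed, patients], patients)
    t = survival["time"].to_numpy(dtype=float)
    e = survival["event"].to_numpy(dtype=int)
    for gene in partners:
        gene_split = dichotomize_by_median(expression.loc[gene, patients], patients)
        comparisons = {
            f"{gene} high vs low": (gene_split == "high").to_numpy(),
            f"{gene}+{seed} HH vs others": (combined_group(seed_split, gene_split) == "HH").to_numpy(),
        }
        for label, in_a in comparisons.items():
            if in_a.sum() == 0 or (~in_a).sum() == 0:
                logger.warning("skipping %s: empty group", label)
                continue
            chi2, p_lr = logrank(t[in_a], e[in_a], t[~in_a], e[~in_a])
            row = {"comparison": label, "n_group": int(in_a.sum()),
                   "n_rest": int((~in_a).sum()), "logrank_chi2": chi2, "logrank_p": p_lr}
            for h in horizons:
                try:
                    zres = os_rate_ztest(t[in_a], e[in_a], t[~in_a], e[~in_a], h)
                except ValueError as exc:
                    logger.warning("Z-test at %g yr for %s skipped: %s", h, label, exc)
                    continue
                row[f"os{h:g}_group"] = zres["rate_a"]
                row[f"os{h:g}_rest"] = zres["rate_b"]
                row[f"z{h:g}"] = zres["z"]
                row[f"p{h:g}"] = zres["p"]
            rows.append(row)
    return pd.DataFrame(rows)
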