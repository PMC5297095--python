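"""Gene-set over-representation analysis for detected clusters.

Hypergeometric upper-tail test of a query gene set against each term of a
GMT collection, with Bonferroni correction over the terms actually tested.
The background universe is supplied by the caller (normally all genes on the
analysed expression matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against.

    Term members are intersected with the background on construction; terms
    left empty by the intersection are dropped.
    """

    terms: dict[str, set]
    descriptions: dict[str, str]
    background: set

    def __post_init__(self) -> None:
        if not self.background:
            raise ValueError("background universe is empty")
        self.terms = {
            t: set(m) & self.background for t, m in self.terms.items()
        }
        self.terms = {t: m for t, m in self.terms.items() if m}
        if not self.terms:
            raise ValueError("no term has members inside the background")

    @classmethod
    def from_gmt(cls, path, background) -> "GeneSetCollection":
        terms: dict[str, set] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                terms[parts[0]] = {g for g in parts[2:] if g}
                descriptions[parts[0]] = parts[1]
        if not terms:
            raise ValueError(f"no gene sets parsed from {path}")
        return cls(terms=terms, descriptions=descriptions, background=set(background))

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for t in sorted(self.terms):
                members = "\t".join(sorted(self.terms[t]))
                fh.write(f"{t}\t{self.descriptions.get(t, '')}\t{members}\n")


def hypergeom_enrich(query, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in every term.

    Genes outside the background are dropped (counted in the log). Per term,
    p_raw = P[X >= overlap] with X ~ Hypergeom(N=background, K=term size,
    n=query size); Bonferroni multiplies by the number of terms tested.
    Sorted by p_raw ascending, ties by term id.
    """
    query = set(query)
    outside = query - collection.background
    if outside:
        logger.info("dropped %d query genes outside the background", len(outside))
    query &= collection.background
    if not query:
        raise ValueError("query is empty after intersection with the background")
    n_bg = len(collection.background)
    n_q = len(query)
    m = len(collection.terms)
    rows = []
    for term, members in collection.terms.items():
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(members), n_q))
        rows.append({
            "term_id": term,
            "description": collection.descriptions.get(term, ""),
            "count": k,
            "query_size": n_q,
            "term_size": len(members),
            "background_size": n_bg,
            "p_raw": min(p, 1.0),
            "p_bonf": min(m * p, 1.0),
        })
    out = pd.DataFrame(rows).sort_values(["p_raw", "term_id"]).reset_index(drop=True)
    return out


def annotate_clusters(clusters, collection: GeneSetCollection,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Run enrichment per cluster; flag Bonferroni-significant rows.

    Also reports, per cluster, the fraction of members covered by its top
    term as ``coverage`` (e.g. "6/10, 60.0%").
    """
    if not clusters:
        raise ValueError("no clusters to annotate")
    frames = []
    for i, c in enumerate(clusters, start=1):
        res = hypergeom_enrich(c.members, collection)
        res.insert(0, "cluster_id", i)
        res["significant"] = res["p_bonf"] < alpha
        top = res.iloc[0]
        cov = f"{int(top['count'])}/{c.size}, {100.0 * top['count'] / c.size:.1f}%"
        res["coverage"] = [cov if j == 0 else "" for j in range(len(res))]
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
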