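"""Sample classification by hierarchical clustering of a gene signature.

Samples are clustered on the hub-gene-plus-seed signature (agglomerative,
average linkage on 1 - Pearson by default, per-gene z-scoring first) and cut
at the root into two classes; class 1 is the control-majority class. The
misclassification count asks how many samples sit in a class whose majority
label differs from their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .expression import CASE, CONTROL, ExpressionMatrix

logger = logging.getLogger(__name__)

_LINKAGES = ("average", "complete", "single")
_DISTANCES = ("one-minus-pearson", "euclidean")


@dataclass
class ClassAssignment:
    """Two-class sample assignment with its confusion against true labels."""

    classes: pd.Series            # sample_id -> 1 or 2
    confusion: pd.DataFrame       # rows class 1/2, columns case/control
    n_misclassified: int
    misclassification_pct: float

    def summary(self) -> dict:
        conf = {f"class{c}_{g}": int(self.confusion.loc[c, g])
                for c in self.confusion.index for g in self.confusion.columns}
        return {
            "n_samples": int(self.classes.size),
            "n_misclassified": self.n_misclassified,
            "misclassification_pct": self.misclassification_pct,
            **conf,
        }


def cluster_samples(
    matrix: ExpressionMatrix,
    genes=None,
    linkage_method: str = "average",
    distance: str = "one-minus-pearson",
    standardize: bool = True,
) -> np.ndarray:
    """Agglomerative merge tree over samples (scipy linkage matrix).

    ``genes`` restricts the matrix to the signature; missing genes are an
    error listing them. Per-gene z-scoring (default on) prevents
    high-variance genes from dominating the distance.
    """
    if linkage_method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if distance not in _DISTANCES:
        raise ValueError(f"distance must be one of {_DISTANCES}")
    if genes is not None:
        missing = [g for g in genes if g not in matrix.values.index]
        if missing:
            raise KeyError(f"signature genes missing from matrix: {missing}")
        values = matrix.values.loc[list(genes)]
    else:
        values = matrix.values
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need >= 2 signature genes and >= 2 samples")

    x = values.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=1, keepdims=True)) / sd
    cols = x.T  # samples as observations
    if distance == "euclidean":
        d = pdist(cols, metric="euclidean")
    else:
        d = pdist(cols, metric="correlation")  # 1 - Pearson r
        d = np.clip(d, 0.0, None)
    return linkage(d, method=linkage_method)


def two_class_cut(merge_tree: np.ndarray, sample_ids, sample_groups) -> ClassAssignment:
    """Cut the dendrogram at its final merge into exactly two classes.

    Class numbering: the control-majority class is class 1; when the control
    fractions tie, the larger class is class 1. Misclassified samples are
    those whose true label differs from their class's majority label.
    """
    sample_ids = list(sample_ids)
    flat = fcluster(merge_tree, t=2, criterion="maxclust")
    labels = pd.Series([sample_groups[s] for s in sample_ids], index=sample_ids)
    raw = pd.Series(flat, index=sample_ids)

    stats = {}
    for c in sorted(raw.unique()):
        in_c = labels[raw == c]
        stats[c] = {
            "n": int(in_c.size),
            "n_control": int((in_c == CONTROL).sum()),
        }
    # order raw classes: class 1 = higher control fraction, tie -> larger class
    order = sorted(stats, key=lambda c: (-stats[c]["n_control"] / stats[c]["n"],
                                         -stats[c]["n"], c))
    remap = {order[0]: 1}
    for c in stats:
        if c not in remap:
            remap[c] = 2
    classes = raw.map(remap)

    confusion = pd.DataFrame(0, index=[1, 2], columns=[CASE, CONTROL])
    for c in (1, 2):
        in_c = labels[classes == c]
        confusion.loc[c, CASE] = int((in_c == CASE).sum())
        confusion.loc[c, CONTROL] = int((in_c == CONTROL).sum())
    n_mis = 0
    for c in (1, 2):
        row = confusion.loc[c]
        if row.sum() == 0:
            continue
        majority = row.idxmax()  # ties: CASE column first; absorbed by pct symmetry
        n_mis += int(row.sum() - row[majority])
    pct = 100.0 * n_mis / len(sample_ids)
    logger.info("two-class cut: %d/%d misclassified (%.1f%%)", n_mis, len(sample_ids), pct)
    return ClassAssignment(classes=classes, confusion=confusion,
                           n_misclassified=n_mis, misclassification_pct=pct)
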