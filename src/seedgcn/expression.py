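"""Expression-matrix containers, I/O, probe collapsing and qPCR quantification.

The in-memory container wraps a pandas DataFrame of log2 expression values
(genes x samples) together with a sample -> group mapping and optional
survival annotation. Matrices are exchanged as plain TSV: header row of
sample identifiers, first column ``gene_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with sample annotation.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique gene (or probe) identifier, columns by unique
        sample identifier, log2 scale, no missing values.
    sample_groups : dict
        Maps sample_id -> ``"case"`` or ``"control"``.
    survival : pandas.DataFrame, optional
        Indexed by sample_id with columns ``time`` (years) and ``event``
        (0/1), for the samples that carry follow-up.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str] = field(default_factory=dict)
    survival: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_groups.get(s) == group]

    def restrict_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        surv = None
        if self.survival is not None:
            surv = self.survival.loc[self.survival.index.intersection(sample_ids)]
        return ExpressionMatrix(
            values=self.values[sample_ids].copy(),
            sample_groups={s: g for s, g in self.sample_groups.items() if s in sample_ids},
            survival=surv,
        )

    def cases_only(self) -> "ExpressionMatrix":
        return self.restrict_samples(self.samples_in_group(CASE))

    def gene(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.values.index:
            raise KeyError(f"gene {gene_id!r} not in matrix")
        return self.values.loc[gene_id].to_numpy(dtype=float)


def read_expression(path, annotation_path, missing_policy: str = "drop") -> ExpressionMatrix:
    """Read an expression TSV plus a sample annotation TSV.

    The matrix file has a header row of sample IDs and a first column
    ``gene_id``; the annotation file has columns ``sample_id``, ``group`` and
    optionally ``time`` / ``event``. Samples are restricted to annotated
    ones; a sample present in the matrix but absent from the annotation is an
    error naming the sample. Rows with missing values are dropped (counted in
    the log) under the default policy, or rejected with ``missing_policy="error"``.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_cols = header[1:]
    dups = sorted({s for s in sample_cols if sample_cols.count(s) > 1})
    if dups:
        raise ValueError(f"duplicate sample columns: {dups}")
    raw = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "gene_id"

    ann = pd.read_csv(annotation_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in ann.columns or "group" not in ann.columns:
        raise ValueError("annotation must have 'sample_id' and 'group' columns")
    ann = ann.set_index("sample_id")
    unknown = [s for s in raw.columns if s not in ann.index]
    if unknown:
        raise ValueError(f"samples in matrix absent from annotation: {unknown}")

    values = raw.astype(float)
    n_missing = int(values.isna().any(axis=1).sum())
    if n_missing:
        if missing_policy == "error":
            raise ValueError(f"{n_missing} gene rows contain missing values")
        values = values.dropna(axis=0)
        logger.info("dropped %d gene rows with missing values", n_missing)

    groups = {s: str(ann.loc[s, "group"]) for s in values.columns}
    bad = {s: g for s, g in groups.items() if g not in (CASE, CONTROL)}
    if bad:
        raise ValueError(f"sample group labels must be 'case'/'control', got: {bad}")

    survival = None
    if "time" in ann.columns and "event" in ann.columns:
        surv = ann.loc[[s for s in values.columns if s in ann.index], ["time", "event"]]
        surv = surv.dropna()
        if len(surv):
            survival = surv.astype({"time": float, "event": int})

    logger.info(
        "read expression matrix: %d genes x %d samples (%d rows dropped)",
        values.shape[0], values.shape[1], n_missing,
    )
    return ExpressionMatrix(values=values, sample_groups=groups, survival=survival)


def write_expression(matrix: ExpressionMatrix, path, annotation_path=None) -> None:
    """Write the matrix (and optionally its annotation) as TSV.

    Values are written with enough digits (repr precision) that a read/write
    round trip preserves them to at least 10 significant digits.
    """
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.12g")
    if annotation_path is not None:
        ann = pd.DataFrame({
            "sample_id": matrix.sample_ids,
            "group": [matrix.sample_groups.get(s, "") for s in matrix.sample_ids],
        })
        if matrix.survival is not None:
            ann = ann.merge(
                matrix.survival.reset_index().rename(columns={"index": "sample_id"}),
                on="sample_id", how="left",
            )
        ann.to_csv(annotation_path, sep="\t", index=False, float_format="%.12g")


def read_probe_map(path) -> dict[str, str]:
    """Two-column TSV ``probe_id<TAB>gene_symbol`` -> dict."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe map needs two columns: probe_id, gene_symbol")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def collapse_probes(matrix: ExpressionMatrix, probe_map: dict[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to gene level by averaging on the log2 scale.

    Genes measured by two or more probes get the per-sample arithmetic mean
    of the probes' log2 values; single-probe genes pass through unchanged.
    Probes mapping to no gene (absent from the map, or mapped to an empty
    symbol) are dropped and counted.
    """
    mapped = pd.Series({p: probe_map.get(p) for p in matrix.values.index})
    keep = mapped.notna() & (mapped != "")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d probes with no gene mapping", n_dropped)
    sub = matrix.values.loc[keep[keep].index]
    if sub.empty:
        raise ValueError("no probes left after collapsing: empty result")
    genes = mapped[keep[keep].index]
    collapsed = sub.groupby(genes.to_dict()).mean()
    collapsed = collapsed.sort_index()
    collapsed.index.name = "gene_id"
    return ExpressionMatrix(values=collapsed, sample_groups=dict(matrix.sample_groups),
                            survival=matrix.survival)


@dataclass
class CtTable:
    """qPCR threshold-cycle values for one target gene.

    Each row: sample, target-gene Ct, reference-gene Ct; exactly one sample
    is flagged as the calibrator that anchors the ddCt comparison.
    """

    sample_ids: list[str]
    target_ct: np.ndarray
    reference_ct: np.ndarray
    calibrator: str

    def __post_init__(self) -> None:
        self.target_ct = np.asarray(self.target_ct, dtype=float)
        self.reference_ct = np.asarray(self.reference_ct, dtype=float)
        if self.calibrator not in self.sample_ids:
            raise ValueError(f"calibrator {self.calibrator!r} not among samples")
        for name, arr in (("target_ct", self.target_ct), ("reference_ct", self.reference_ct)):
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name} must be finite and positive")


def ddct_relative_expression(table: CtTable) -> pd.Series:
    """Relative expression by the comparative Ct method, 2^(-ddCt).

    dCt = target Ct - reference Ct per sample; ddCt = dCt - dCt(calibrator);
    the calibrator sample therefore has relative expression exactly 1.
    """
    dct = table.target_ct - table.reference_ct
    cal_idx = table.sample_ids.index(table.calibrator)
    ddct = dct - dct[cal_idx]
    return pd.Series(np.exp2(-ddct), index=pd.Index(table.sample_ids, name="sample_id"),
                     name="relative_expression")
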