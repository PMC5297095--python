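"""Synthetic case/control cohorts with a planted seed-correlated module.

A two-factor Gaussian model generates log2 expression with the structure the
pipeline assumes:

* a module factor ``f`` drives the planted co-expression module and the seed
  gene, so the module genes correlate with the seed and with each other
  (population correlation between genes with loadings a, b and noise sd s is
  a*b / sqrt((a^2+s^2)(b^2+s^2)));
* a confounder factor ``h`` ("glycolysis-like") drives the confounder
  readout gene and a block of confounder-mediated genes, and leaks into the
  seed with loading gamma — those genes correlate with the seed marginally
  but their partial correlation given the confounder readout is ~0 by
  construction;
* case samples get additive log2 shifts (the planted differential effects);
* survival times are exponential with hazard lambda0 * exp(beta * z), where
  z is the z-scored per-sample signature score, with independent uniform
  censoring.

Everything derives from one ``numpy`` Generator seeded by ``rng_seed``: the
same spec and seed reproduce the cohort bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .expression import CASE, CONTROL, ExpressionMatrix


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults describe a mid-sized two-arm expression study: 90 cases vs 60
    controls over 500 genes, a 20-gene module with loadings U[0.6, 0.9] on
    the shared factor (seed loading 0.9), log2 noise sd 0.7, a confounder
    pathway (gamma = 0.5 into the seed, readout loading 2.0, eight
    confounder-mediated genes at loading 0.8), per-gene log2 case shifts
    drawn from U[0.8, 3.0] on the planted signal genes (the seed pinned at
    the midpoint) plus 30 background DE genes (half down-shifted), and
    survival with
    baseline hazard 0.15/yr, signature log-hazard 1.0 and uniform censoring
    on [0, 10] years.
    """

    n_cases: int = 90
    n_controls: int = 60
    n_genes: int = 500
    seed_gene: str = "ALDOA"
    confounder_gene: str = "HK2"
    module_size: int = 20
    module_loading_range: tuple[float, float] = (0.6, 0.9)
    seed_loading: float = 0.9
    confounder_to_seed: float = 0.5      # gamma: h -> seed
    confounder_loading: float = 2.0      # h -> confounder readout gene
    n_confounder_only: int = 8
    confounder_only_loading: float = 0.8
    de_shift_range: tuple[float, float] = (0.8, 3.0)  # log2 case shifts, drawn per gene
    n_background_de: int = 30
    control_factor_scale: float = 1.0    # module-factor amplitude in controls
    noise_sd: float = 0.7
    baseline_hazard: float = 0.15        # events per year
    signature_beta: float = 1.0          # log-hazard per signature sd
    censor_window: float = 10.0          # years of uniform censoring
    rng_seed: int = 0

    def validate(self) -> None:
        positive = ["n_cases", "n_controls", "n_genes", "module_size", "noise_sd",
                    "baseline_hazard"]
        for name in positive:
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"spec field {name!r} must be positive")
        for name in ["seed_loading", "confounder_to_seed", "confounder_loading",
                     "confounder_only_loading", "signature_beta",
                     "control_factor_scale", "censor_window"]:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"spec field {name!r} must be finite")
        for name in ("module_loading_range", "de_shift_range"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 <= lo <= hi):
                raise ValueError(f"spec field {name!r} must be ordered and finite")
        reserved = 2 + self.module_size + self.n_confounder_only
        if reserved + self.n_background_de >= self.n_genes:
            raise ValueError("spec field 'n_genes' too small for the planted structure")


def _gene_names(spec: CohortSpec) -> dict[str, list[str]]:
    module = [f"MOD{i:03d}" for i in range(1, spec.module_size + 1)]
    conf_only = [f"CMF{i:03d}" for i in range(1, spec.n_confounder_only + 1)]
    n_bg = spec.n_genes - 2 - spec.module_size - spec.n_confounder_only
    background = [f"BG{i:04d}" for i in range(1, n_bg + 1)]
    return {"module": module, "conf_only": conf_only, "background": background}


def generate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Generate (expression matrix, sample annotation, truth manifest).

    The annotation has columns sample_id / group plus time / event from
    :func:`generate_survival`. The truth manifest records the planted module
    members with their loadings, the confounder-mediated genes, the
    background DE genes and the survival parameters, for test assertions.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    names = _gene_names(spec)
    n = spec.n_cases + spec.n_controls
    sample_ids = [f"T{i:03d}" for i in range(1, spec.n_cases + 1)] + \
                 [f"N{i:03d}" for i in range(1, spec.n_controls + 1)]
    is_case = np.array([1] * spec.n_cases + [0] * spec.n_controls, dtype=float)

    f = rng.standard_normal(n)          # module factor
    h = rng.standard_normal(n)          # confounder factor
    f_scale = np.where(is_case == 1, 1.0, spec.control_factor_scale)
    f_eff = f * f_scale

    lo, hi = spec.module_loading_range
    loadings = rng.uniform(lo, hi, size=spec.module_size)

    gene_ids = [spec.seed_gene, spec.confounder_gene] + names["module"] + \
               names["conf_only"] + names["background"]
    baselines = rng.uniform(5.0, 9.0, size=len(gene_ids))
    # per-gene case shifts: fold changes vary gene to gene as in real cohorts
    # (a uniform shift would also leave profile *shapes* identical between
    # groups, hiding the case/control split from correlation distances)
    dlo, dhi = spec.de_shift_range
    n_planted = 2 + spec.module_size + spec.n_confounder_only
    planted_shifts = rng.uniform(dlo, dhi, size=n_planted)
    # the seed anchors every downstream stage; pin its shift mid-range so it
    # clears the DEG filters with certainty rather than by draw
    planted_shifts[0] = 0.5 * (dlo + dhi)
    bg_shifts = rng.uniform(dlo, dhi, size=spec.n_background_de)

    values = np.empty((len(gene_ids), n))
    noise = lambda: rng.normal(0.0, spec.noise_sd, size=n)
    shifts: dict[str, float] = {}
    row = 0
    # seed gene: module factor + confounder leak + case shift
    shifts[spec.seed_gene] = planted_shifts[0]
    values[row] = baselines[row] + planted_shifts[0] * is_case + \
        spec.seed_loading * f_eff + spec.confounder_to_seed * h + noise()
    row += 1
    # confounder readout: driven by h, shifted in cases
    shifts[spec.confounder_gene] = planted_shifts[1]
    values[row] = baselines[row] + planted_shifts[1] * is_case + \
        spec.confounder_loading * h + noise()
    row += 1
    for k, (g, lam) in enumerate(zip(names["module"], loadings)):
        shifts[g] = planted_shifts[2 + k]
        values[row] = baselines[row] + shifts[g] * is_case + lam * f_eff + noise()
        row += 1
    for k, g in enumerate(names["conf_only"]):
        shifts[g] = planted_shifts[2 + spec.module_size + k]
        values[row] = baselines[row] + shifts[g] * is_case + \
            spec.confounder_only_loading * h + noise()
        row += 1
    # background: first n_background_de genes get +/- shifts, rest pure noise
    bg_dirs = {}
    for i, g in enumerate(names["background"]):
        shift = 0.0
        if i < spec.n_background_de:
            shift = bg_shifts[i] if i % 2 == 0 else -bg_shifts[i]
            bg_dirs[g] = shift
            shifts[g] = shift
        values[row] = baselines[row] + shift * is_case + noise()
        row += 1

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                            columns=sample_ids),
        sample_groups={s: (CASE if c else CONTROL)
                       for s, c in zip(sample_ids, is_case)},
    )
    annotation = pd.DataFrame({
        "sample_id": sample_ids,
        "group": [CASE if c else CONTROL for c in is_case],
    })

    # survival driven by the planted signature (seed + module genes)
    sig_rows = [spec.seed_gene] + names["module"]
    score = matrix.values.loc[sig_rows].mean(axis=0).to_numpy()
    annotation = generate_survival(annotation, score, spec, rng)
    matrix.survival = annotation.set_index("sample_id")[["time", "event"]].astype(
        {"time": float, "event": int})

    truth = {
        "seed_gene": spec.seed_gene,
        "confounder_gene": spec.confounder_gene,
        "module_genes": names["module"],
        "module_loadings": dict(zip(names["module"], loadings.tolist())),
        "top_loading_gene": names["module"][int(np.argmax(loadings))],
        "confounder_only_genes": names["conf_only"],
        "case_shifts": shifts,
        "background_de": bg_dirs,
        "signature_beta": spec.signature_beta,
        "baseline_hazard": spec.baseline_hazard,
    }
    return matrix, annotation, truth


def generate_survival(annotation: pd.DataFrame, signature_score, spec: CohortSpec,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Attach exponential survival with signature-linked hazard.

    hazard_i = lambda0 * exp(beta * z_i) with z the z-scored signature score;
    censoring is uniform on [0, censor_window]; event = 1 iff the death time
    precedes the censoring time.
    """
    if not np.isfinite(spec.signature_beta) or not np.isfinite(spec.baseline_hazard):
        raise ValueError("signature_beta and baseline_hazard must be finite")
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    score = np.asarray(signature_score, dtype=float)
    n = len(annotation)
    if score.size != n:
        raise ValueError("signature score must align with the annotation")
    sd = score.std(ddof=0)
    z = (score - score.mean()) / sd if sd > 0 else np.zeros(n)
    hazard = spec.baseline_hazard * np.exp(spec.signature_beta * z)
    death = rng.exponential(1.0 / hazard)
    censor = rng.uniform(0.0, spec.censor_window, size=n) if spec.censor_window > 0 \
        else np.zeros(n)
    out = annotation.copy()
    out["time"] = np.minimum(death, censor)
    out["event"] = (death <= censor).astype(int)
    return out


def generate_gmt(spec: CohortSpec, module_genes, all_genes, n_decoys: int = 50,
                 decoy_size_range: tuple[int, int] = (10, 40),
                 rng: np.random.Generator | None = None) -> GeneSetCollection:
    """A gene-set collection with one true term (= planted module) + decoys.

    Decoy terms draw random genes from the full universe with sizes uniform
    on ``decoy_size_range``. Deterministic given the generator state.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed + 1)
    all_genes = list(all_genes)
    terms = {"TERM_MODULE": set(module_genes)}
    descriptions = {"TERM_MODULE": "planted co-expression module"}
    lo, hi = decoy_size_range
    for i in range(1, n_decoys + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(all_genes, size=min(size, len(all_genes)), replace=False)
        tid = f"DECOY{i:03d}"
        terms[tid] = set(members.tolist())
        descriptions[tid] = "random decoy gene set"
    return GeneSetCollection(terms=terms, descriptions=descriptions,
                             background=set(all_genes))


def write_cohort(spec: CohortSpec, out_dir) -> dict:
    """Write expression TSV, annotation TSV, GMT and truth manifest to a directory."""
    from .expression import write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, annotation, truth = generate_cohort(spec)
    write_expression(matrix, out / "expression.tsv")
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False, float_format="%.12g")
    gmt = generate_gmt(spec, truth["module_genes"], matrix.gene_ids)
    gmt.to_gmt(out / "genesets.gmt")
    manifest = {"spec": asdict(spec), "truth": truth}
    with open(out / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
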