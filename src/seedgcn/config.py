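"""Pipeline configuration: one YAML document drives every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths.

    Thresholds default to the analysis' standard settings: DEG call at
    adjusted p < 0.05 with linear fold change > 1.5, seed-association screen
    at p < 0.05, network edges at Pearson r >= 0.7, clusters of size >= 3 and
    density >= 0.5 kept at quality p < 0.05, Bonferroni enrichment at 0.05,
    top-10 hub lists, and survival horizons at 3 and 5 years.
    """

    expression_path: str = ""
    annotation_path: str = ""
    probe_map_path: str | None = None
    gmt_path: str | None = None
    out_dir: str = "seedgcn_out"

    seed_gene: str = "ALDOA"
    deg_alpha: float = 0.05
    fc_min: float = 1.5
    aa_alpha: float = 0.05
    aa_use_adjusted: bool = False
    r_min: float = 0.7
    cluster_min_size: int = 3
    cluster_min_density: float = 0.5
    cluster_alpha: float = 0.05
    cluster_penalty: float = 2.0
    cluster_overlap_max: float = 0.8
    enrich_alpha: float = 0.05
    hub_k: int = 10
    confounders: list[str] = field(default_factory=list)
    survival_horizons: list[float] = field(default_factory=lambda: [3.0, 5.0])
    classify_linkage: str = "average"
    classify_distance: str = "one-minus-pearson"
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("deg_alpha", "aa_alpha", "cluster_alpha", "enrich_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.fc_min < 1:
            raise ValueError(f"fc_min must be >= 1, got {self.fc_min}")
        if not -1 <= self.r_min <= 1:
            raise ValueError(f"r_min must lie in [-1, 1], got {self.r_min}")
        if self.cluster_min_size < 1:
            raise ValueError("cluster_min_size must be >= 1")
        if not 0 <= self.cluster_min_density <= 1:
            raise ValueError("cluster_min_density must lie in [0, 1]")
        if not 0 <= self.cluster_overlap_max <= 1:
            raise ValueError("cluster_overlap_max must lie in [0, 1]")
        if self.hub_k < 1:
            raise ValueError("hub_k must be >= 1")
        if not self.seed_gene:
            raise ValueError("seed_gene must be non-empty")
        for h in self.survival_horizons:
            if h <= 0:
                raise ValueError("survival horizons must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return asdict(self)
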