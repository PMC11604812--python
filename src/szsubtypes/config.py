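"""Pipeline configuration: one flat record, YAML/JSON round-trippable."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every knob of the pipeline with its default.

    Thresholds follow the published analysis: DE selection at |logFC| > 0.1
    and FDR q < 0.05; enrichment significance at Bonferroni-adjusted
    p < 0.05; the top third of the importance ranking feeds enrichment.
    """

    # paths (unused when running fully in memory)
    expression: str | None = None
    metadata: str | None = None
    probe_map: str | None = None
    gmt: str | None = None
    outdir: str = "results"

    # thresholds
    min_abs_logfc: float = 0.1
    max_q: float = 0.05
    bonferroni_alpha: float = 0.05
    keep_fraction: float = 0.5
    top_fraction: float = 1.0 / 3.0
    threshold: float = 0.5

    # algorithm knobs
    collapse_method: str = "mean"
    k: int | None = None  # None -> elbow selection
    k_max: int = 6
    n_init: int = 50
    standardize: bool = True
    recluster_loo: bool = False
    lambda_grid: list[float] = field(
        default_factory=lambda: [
            0.01, 0.03162, 0.1, 0.3162, 1.0, 1.778, 3.162, 5.623, 10.0, 17.78,
            31.62, 100.0,
        ]
    )
    cv_folds: int = 5
    cv_rule: str = "1se"
    harmonization: str = "robust_zscore"

    # synthetic-cohort knobs (simulate / validate subcommands)
    n_genes: int = 5000
    n_datasets: int = 5
    coverage: float = 0.9

    seed: int = 0

    def validate(self) -> None:
        for name, lo, hi in [
            ("max_q", 0.0, 1.0),
            ("bonferroni_alpha", 0.0, 1.0),
            ("top_fraction", 0.0, 1.0),
            ("threshold", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name}={v} must lie in ({lo}, {hi})")
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ValueError("keep_fraction must lie in (0, 1]")
        if self.min_abs_logfc < 0:
            raise ValueError("min_abs_logfc must be >= 0")
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda_grid entries must be positive")
        if self.cv_rule not in ("min", "1se"):
            raise ValueError("cv_rule must be 'min' or '1se'")
        if self.harmonization not in ("robust_zscore", "zscore_per_gene", "none"):
            raise ValueError(
                "harmonization must be robust_zscore, zscore_per_gene or none"
            )
        if self.collapse_method not in ("mean", "median", "max_variance"):
            raise ValueError("collapse_method must be mean, median or max_variance")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)
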