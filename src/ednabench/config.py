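"""Pipeline configuration: the run's thresholds, options and file paths.

Centralizes the analysis constants — per-locus assignment presets, filter
thresholds, test options — validated on load; unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # inputs (all None -> simulate the default study scenario)
    counts_path: str | None = None
    sample_meta_path: str | None = None
    taxon_meta_path: str | None = None
    paper_variant: bool = False
    # filter thresholds
    min_run_count: int = 10
    crosstalk_min_total: int = 10
    ratio_min_total: int = 20
    # analysis options
    top_n_bacteria: int = 150
    pca_top_n: int = 50
    pca_transform: str = "logratio"
    anova_ss_type: int = 2
    n_permutations: int = 9999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_run_count < 1 or self.crosstalk_min_total < 1:
            raise ValueError("count thresholds must be >= 1")
        if self.ratio_min_total < 1:
            raise ValueError("ratio_min_total must be >= 1")
        if self.pca_transform not in ("logratio", "clr"):
            raise ValueError(f"unknown transform {self.pca_transform!r}")
        if self.anova_ss_type not in (1, 2):
            raise ValueError("anova_ss_type must be 1 or 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def load_config(path) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
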