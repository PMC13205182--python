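"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of one pipeline run.

    Defaults are the analysis conditions: 100,000 MCMC iterations with
    10,000 burn-in, up to 5 candidate subtypes, a cohort-wide mutation
    frequency threshold of 150, stage-gene selection at |rho| > 0.35 and
    FDR < 0.05, ssGSEA weight exponent 0.25 and a top-5% AUCell window.
    """

    seed: int = 0
    n_subtypes: int = 2
    n_subtypes_max: int = 5
    select_subtypes: bool = False  # run CV model selection instead of fixed C
    mcmc_iters: int = 100_000
    burn_in: int = 10_000
    n_starts: int = 3
    cv_iters: int = 2_000  # reduced MCMC used inside cross-validation
    cv_folds: int = 5
    alpha: float = 0.05  # spurious-call rate of the noise model
    beta: float = 0.05  # missed-call rate
    min_mutation_count: int = 150
    rho_threshold: float = 0.35
    fdr_threshold: float = 0.05
    ssgsea_alpha: float = 0.25
    aucell_top_frac: float = 0.05
    synthetic: bool = True
    n_samples: int = 400  # synthetic cohort size
    n_null_genes: int = 990
    maf_path: str | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    gmt_path: str | None = None
    family_map_path: str | None = None
    out_dir: str = "stagepath_run"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.burn_in >= self.mcmc_iters:
            raise ValueError("burn_in must be smaller than mcmc_iters")
        if not 0 < self.rho_threshold < 1:
            raise ValueError("rho_threshold must be in (0, 1)")
        if not 0 < self.aucell_top_frac < 1:
            raise ValueError("aucell_top_frac must be in (0, 1)")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.n_subtypes < 1 or self.n_subtypes_max < 1:
            raise ValueError("subtype counts must be >= 1")
        if not self.synthetic and not self.maf_path:
            raise ValueError("non-synthetic runs need a mutation table (maf_path)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
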